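"""Redundant 1D dictionaries for separable 2D sparse approximation.

A separable 2D dictionary is the tensor product of two 1D dictionaries;
every 2D atom is an outer product ``dx @ dy.T`` and is never materialised
as a column of an explicit 2D dictionary.  This module builds the 1D
ingredients:

* a redundant cosine dictionary ``D_C`` (atom ``n`` has components
  ``w_c(n) * cos(pi*(2i-1)*(n-1) / (2M))``, ``i = 1..N``),
* a redundant sine dictionary ``D_S`` (components
  ``w_s(n) * sin(pi*(2i-1)*n / (2M))``),
* dictionaries generated by translating short prototype atoms across the
  block (one family for pixel-intensity work, one for wavelet-coefficient
  work),
* mixed unions ``D_C | D_S | D_L`` used by the encoder.

``w_c`` and ``w_s`` are the normalisation factors that make every atom a
unit vector; the redundancy parameter defaults to ``M = 2N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: absolute tolerance on the unit norm of every atom
NORM_TOL = 1e-10

#: two atoms are considered duplicates when |<a, b>| >= 1 - DUPLICATE_TOL
DUPLICATE_TOL = 1e-8


class DictionaryError(ValueError):
    """Invalid dictionary configuration or construction failure."""


@dataclass(frozen=True)
class PrototypeAtom:
    """A short generating waveform translated across the block.

    Parameters
    ----------
    values : array-like
        Finite-support samples of the prototype (not all zero).
    step : int
        Translation stride in pixels (default 1).
    id : str
        Human-readable tag used in atom provenance labels.
    """

    values: tuple
    step: int = 1
    id: str = "prototype"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise DictionaryError("prototype values must be a nonempty 1D sequence")
        if not np.any(vals != 0):
            raise DictionaryError(f"prototype {self.id!r} is identically zero")
        if self.step < 1:
            raise DictionaryError("translation step must be a positive integer")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @property
    def support(self) -> int:
        return len(self.values)


@dataclass
class Dictionary1D:
    """An ordered redundant set of unit-norm 1D atoms.

    Attributes
    ----------
    atoms : ndarray, shape (length, size)
        One column per atom.
    labels : list of str
        Per-atom provenance tag: ``"cosine"``, ``"sine"`` or
        ``"prototype:<id>"``.
    """

    atoms: np.ndarray
    labels: list = field(default_factory=list)
    norm_tol: float = NORM_TOL

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2 or self.atoms.size == 0:
            raise DictionaryError("atom matrix must be a nonempty 2D array")
        if len(self.labels) != self.atoms.shape[1]:
            raise DictionaryError("one label per atom is required")

    @property
    def length(self) -> int:
        """Atom length N (pixels)."""
        return self.atoms.shape[0]

    @property
    def size(self) -> int:
        """Number of atoms M."""
        return self.atoms.shape[1]

    def validate(self, check_duplicates: bool = True) -> None:
        """Raise if any atom is not unit-norm or two atoms coincide."""
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > self.norm_tol):
            worst = float(np.max(np.abs(norms - 1.0)))
            raise DictionaryError(f"atom norms deviate from 1 by up to {worst:g}")
        if check_duplicates:
            gram = np.abs(self.atoms.T @ self.atoms)
            np.fill_diagonal(gram, 0.0)
            if np.any(gram >= 1.0 - DUPLICATE_TOL):
                raise DictionaryError("dictionary contains (near-)duplicate atoms")


# ---------------------------------------------------------------------------
# trigonometric dictionaries
# ---------------------------------------------------------------------------

def build_cosine_dictionary(N: int, M: int | None = None) -> Dictionary1D:
    """Redundant cosine dictionary: M atoms of length N, unit-normalised.

    Atom ``n`` (1-based) has unnormalised components
    ``cos(pi*(2i-1)*(n-1) / (2M))`` for ``i = 1..N``.  With ``M = 2N``
    (the default) the set is redundant by a factor of two.
    """
    if N < 1 or (M is not None and M < 1):
        raise DictionaryError("N and M must be positive integers")
    if M is None:
        M = 2 * N
    i = np.arange(1, N + 1)[:, None]
    n = np.arange(1, M + 1)[None, :]
    raw = np.cos(np.pi * (2 * i - 1) * (n - 1) / (2 * M))
    atoms = raw / np.linalg.norm(raw, axis=0)
    return Dictionary1D(atoms, ["cosine"] * M)


def build_sine_dictionary(N: int, M: int | None = None) -> Dictionary1D:
    """Redundant sine dictionary: atom ``n`` has components
    ``w_s(n) * sin(pi*(2i-1)*n / (2M))``, ``i = 1..N``."""
    if N < 1 or (M is not None and M < 1):
        raise DictionaryError("N and M must be positive integers")
    if M is None:
        M = 2 * N
    i = np.arange(1, N + 1)[:, None]
    n = np.arange(1, M + 1)[None, :]
    raw = np.sin(np.pi * (2 * i - 1) * n / (2 * M))
    norms = np.linalg.norm(raw, axis=0)
    if np.any(norms < 1e-14):
        raise DictionaryError("a sine atom normalised to numerical zero")
    atoms = raw / norms
    return Dictionary1D(atoms, ["sine"] * M)


# ---------------------------------------------------------------------------
# translated-prototype dictionaries
# ---------------------------------------------------------------------------

# Defaults: short symmetric pulses for pixel-intensity blocks and short
# oscillating pulses for wavelet-coefficient blocks.  Translated with stride
# 1; translates that would be clipped at the block boundary are excluded, so
# every atom has full support inside the block.
PIXEL_PROTOTYPES = (
    PrototypeAtom((1.0,), id="impulse"),
    PrototypeAtom((1.0, 2.0, 1.0), id="hat3"),
    PrototypeAtom((1.0, 2.0, 3.0, 2.0, 1.0), id="hat5"),
)

WAVELET_PROTOTYPES = (
    PrototypeAtom((1.0,), id="impulse"),
    PrototypeAtom((1.0, -1.0), id="osc2"),
    PrototypeAtom((1.0, -2.0, 1.0), id="osc3"),
)


def build_translate_dictionary(prototypes, N: int) -> Dictionary1D:
    """All full-support integer translates of each prototype, unit-normalised.

    For a prototype of support ``L`` and stride ``s`` the translates are the
    offsets ``0, s, 2s, ...`` with ``offset + L <= N``.
    """
    prototypes = list(prototypes)
    if not prototypes:
        raise DictionaryError("at least one prototype atom is required")
    cols, labels = [], []
    for proto in prototypes:
        if proto.support > N:
            raise DictionaryError(
                f"prototype {proto.id!r} support {proto.support} exceeds length {N}"
            )
        vals = np.asarray(proto.values, dtype=float)
        vals = vals / np.linalg.norm(vals)
        for offset in range(0, N - proto.support + 1, proto.step):
            atom = np.zeros(N)
            atom[offset : offset + proto.support] = vals
            cols.append(atom)
            labels.append(f"prototype:{proto.id}")
    return Dictionary1D(np.column_stack(cols), labels)


def load_prototypes(path) -> list:
    """Read prototype atoms from a text file, one per line,
    whitespace-separated real values."""
    protos = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = tuple(float(tok) for tok in line.split())
        protos.append(PrototypeAtom(vals, id=f"file{ln}"))
    if not protos:
        raise DictionaryError(f"no prototype atoms found in {path}")
    return protos


# ---------------------------------------------------------------------------
# mixed dictionaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DictionaryConfig:
    """Settings for the mixed dictionary.

    ``M`` is the trigonometric atom count per family (None means ``2N``);
    ``prototype_file`` optionally replaces the built-in prototype family
    with vectors read from a text file.
    """

    M: int | None = None
    prototype_file: str | None = None

    def describe(self) -> str:
        return f"M={self.M if self.M is not None else 'auto'};protos={self.prototype_file or 'default'}"


def build_mixed_dictionary(
    domain: str, N: int, config: DictionaryConfig | None = None
) -> Dictionary1D:
    """Union ``D_C | D_S | D_L(domain)`` in that fixed order.

    The atom ordering (cosine block, sine block, translate block, each in
    natural index order) is fixed so that linearised stream indices are
    reproducible across runs.  The same dictionary serves both the x and y
    directions for square blocks.
    """
    if domain not in ("pixel", "wavelet"):
        raise DictionaryError(f"unknown domain {domain!r}")
    config = config or DictionaryConfig()
    M = config.M if config.M is not None else 2 * N
    if config.prototype_file is not None:
        protos = load_prototypes(config.prototype_file)
    else:
        protos = PIXEL_PROTOTYPES if domain == "pixel" else WAVELET_PROTOTYPES
    dc = build_cosine_dictionary(N, M)
    ds = build_sine_dictionary(N, M)
    dl = build_translate_dictionary(protos, N)
    atoms = np.concatenate([dc.atoms, ds.atoms, dl.atoms], axis=1)
    labels = dc.labels + ds.labels + dl.labels
    return Dictionary1D(atoms, labels)
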