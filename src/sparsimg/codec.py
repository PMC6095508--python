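"""Quantisation, stream serialisation, HDF5 container and rate control.

The coefficients of every block decomposition are uniformly quantised,

    m = ceil((|c| - theta) / Delta)   if |c| >= theta, else dropped,

with the discard threshold fixed at ``theta = 1.3 * Delta``.  Atom index
pairs are linearised (``o = (lx - 1) * My + ly``), sorted ascending and
delta-coded; the per-block index strings are concatenated with ``0``
separators into the stream ``st_ind``, while the quantised magnitudes and
sign bits are plainly concatenated into ``st_cf`` and ``st_sg``.  Decoding
maps magnitudes back to mid-bin reconstruction levels
``|c| = Delta * m + (theta - Delta / 2)``.

The three streams plus a self-describing header live in an HDF5 container;
no entropy coding is applied — the only size lever is the smallest
unsigned integer width that holds each stream, with sign bits packed eight
per byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import h5py

from .blocks import (
    ApproximationResult,
    DomainSpec,
    PartitionSpec,
    approximate_image,
    reconstruct_image,
    _DictCache,
    _psnr,
)
from .dictionaries import DictionaryConfig
from .pursuit import BlockDecomposition


class CorruptContainerError(ValueError):
    """The stream data violate the container's own header contract."""


@dataclass(frozen=True)
class QuantizerSpec:
    """Uniform quantiser: bin width ``delta`` and discard threshold
    ``theta = theta_factor * delta`` (1.3 by default, used for all images)."""

    delta: float
    theta_factor: float = 1.3

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")

    @property
    def theta(self) -> float:
        return self.theta_factor * self.delta


@dataclass
class QuantizedDecomposition:
    """Integer magnitudes, sign bits and sorted linearised indices of the
    surviving coefficients of one block."""

    indices: np.ndarray    # strictly ascending, >= 1
    magnitudes: np.ndarray  # >= 1
    signs: np.ndarray      # 0 = +, 1 = -
    block_id: int = 0

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.int64)
        self.signs = np.asarray(self.signs, dtype=np.uint8)
        if not (len(self.indices) == len(self.magnitudes) == len(self.signs)):
            raise ValueError("indices, magnitudes and signs must have equal length")
        if len(self.indices):
            if self.indices.min() < 1:
                raise ValueError("linearised indices must be >= 1")
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("linearised indices must be strictly ascending")
            if self.magnitudes.min() < 1:
                raise ValueError("quantised magnitudes must be >= 1")

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass
class SparseImageCode:
    """The three concatenated streams plus a self-describing header.

    ``st_ind`` holds, per block, the first sorted linearised index followed
    by successive differences; blocks are separated by ``0`` (so exactly
    ``Q - 1`` separators).  ``st_cf`` and ``st_sg`` are plain
    concatenations of the magnitudes and sign bits.
    """

    st_ind: np.ndarray
    st_cf: np.ndarray
    st_sg: np.ndarray
    header: dict = field(default_factory=dict)

    @property
    def n_coefficients(self) -> int:
        return len(self.st_cf)


# ---------------------------------------------------------------------------
# index mapping and quantisation
# ---------------------------------------------------------------------------

def map_pair_to_index(lx: int, ly: int, My: int) -> int:
    """Bijective 1-based linearisation ``o = (lx - 1) * My + ly``."""
    if ly < 1 or ly > My or lx < 1:
        raise ValueError(f"index pair ({lx}, {ly}) out of range for My={My}")
    return (lx - 1) * My + ly


def map_index_to_pair(o: int, My: int) -> tuple:
    """Inverse of :func:`map_pair_to_index`."""
    if o < 1:
        raise ValueError("linearised index must be >= 1")
    return ((o - 1) // My + 1, (o - 1) % My + 1)


def quantize_magnitude(c_abs: float, qspec: QuantizerSpec) -> int:
    """``ceil((|c| - theta)/Delta)`` for ``|c| >= theta``, else 0."""
    if c_abs < qspec.theta:
        return 0
    return int(np.ceil((c_abs - qspec.theta) / qspec.delta))


def dequantize_magnitude(m: int, qspec: QuantizerSpec) -> float:
    """Mid-bin reconstruction ``Delta * m + (theta - Delta / 2)``."""
    if m < 1:
        raise ValueError("quantised magnitude must be >= 1")
    return qspec.delta * m + (qspec.theta - qspec.delta / 2.0)


def quantize_block(
    dec: BlockDecomposition, qspec: QuantizerSpec, My: int, block_id: int = 0
) -> QuantizedDecomposition:
    """Quantise one decomposition and sort by linearised atom index.

    Coefficients whose magnitude falls below ``theta`` — or quantises to
    zero at the bin boundary — are dropped together with their atoms.
    """
    os_, ms, ss = [], [], []
    for (lx, ly), c in zip(dec.pairs, dec.coefficients):
        m = quantize_magnitude(abs(float(c)), qspec)
        if m < 1:
            continue
        os_.append(map_pair_to_index(lx, ly, My))
        ms.append(m)
        ss.append(0 if c >= 0 else 1)
    if not os_:
        return QuantizedDecomposition(
            np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.uint8),
            block_id,
        )
    order = np.argsort(np.asarray(os_))
    return QuantizedDecomposition(
        np.asarray(os_)[order], np.asarray(ms)[order], np.asarray(ss)[order],
        block_id,
    )


# ---------------------------------------------------------------------------
# stream (de)serialisation
# ---------------------------------------------------------------------------

def encode_streams(blocks, Q: int | None = None) -> SparseImageCode:
    """Concatenate per-block quantised decompositions into the three
    streams, delta-coding the sorted indices with ``0`` block separators."""
    blocks = list(blocks)
    if Q is None:
        Q = len(blocks)
    if len(blocks) != Q:
        raise ValueError(f"expected {Q} blocks, got {len(blocks)}")
    ind, cf, sg = [], [], []
    for qi, qd in enumerate(blocks):
        if qi > 0:
            ind.append(0)
        if qd.k:
            deltas = np.diff(qd.indices)
            if len(deltas) and deltas.min() < 1:
                raise ValueError("block indices are not strictly ascending")
            ind.append(int(qd.indices[0]))
            ind.extend(int(d) for d in deltas)
            cf.extend(int(m) for m in qd.magnitudes)
            sg.extend(int(s) for s in qd.signs)
    return SparseImageCode(
        np.asarray(ind, dtype=np.int64),
        np.asarray(cf, dtype=np.int64),
        np.asarray(sg, dtype=np.uint8),
        header={"Q": Q},
    )


def decode_streams(code: SparseImageCode):
    """Exact inverse of :func:`encode_streams`.

    Raises :class:`CorruptContainerError` when the separator count does not
    match ``Q - 1``, stream lengths disagree, or a cumulative index
    overflows the dictionary size recorded in the header (when present).
    """
    Q = int(code.header["Q"])
    st_ind = np.asarray(code.st_ind, dtype=np.int64)
    n_sep = int(np.count_nonzero(st_ind == 0))
    if n_sep != Q - 1:
        raise CorruptContainerError(f"expected {Q - 1} separators, found {n_sep}")
    max_index = code.header.get("max_index")
    if len(code.st_cf) != len(code.st_sg):
        raise CorruptContainerError("coefficient and sign streams differ in length")

    segments: list[list[int]] = [[]]
    for v in st_ind:
        if v == 0:
            segments.append([])
        else:
            segments[-1].append(int(v))
    total_k = sum(len(s) for s in segments)
    if total_k != len(code.st_cf):
        raise CorruptContainerError(
            f"index stream holds {total_k} coefficients, "
            f"coefficient stream holds {len(code.st_cf)}"
        )

    out = []
    pos = 0
    for qi, seg in enumerate(segments):
        idx = np.cumsum(np.asarray(seg, dtype=np.int64)) if seg else np.zeros(0, np.int64)
        if len(idx) and max_index is not None and idx[-1] > max_index:
            raise CorruptContainerError(
                f"block {qi}: index {int(idx[-1])} exceeds dictionary size {max_index}"
            )
        k = len(idx)
        out.append(
            QuantizedDecomposition(
                idx,
                code.st_cf[pos : pos + k],
                code.st_sg[pos : pos + k],
                block_id=qi,
            )
        )
        pos += k
    return out


# ---------------------------------------------------------------------------
# end-to-end image coding
# ---------------------------------------------------------------------------

def _dict_hash(config: DictionaryConfig | None) -> str:
    text = (config or DictionaryConfig()).describe()
    return hashlib.sha1(text.encode()).hexdigest()[:16]


def _block_dims(pspec: PartitionSpec):
    """Per-block (nx, ny) in row-major partition order."""
    return [
        (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        for sl in pspec.block_slices()
    ]


def quantize_decompositions(decompositions, pspec, dspec, dict_config, qspec):
    """Quantise every block against its own y-dictionary size."""
    cache = _DictCache(dict_config)
    out = []
    for qi, (dec, (nx, ny)) in enumerate(zip(decompositions, _block_dims(pspec))):
        My = cache.get(dspec.domain, ny).size
        out.append(quantize_block(dec, qspec, My, block_id=qi))
    return out


def dequantize_decompositions(qblocks, pspec, dspec, dict_config, qspec):
    """Map quantised blocks back to real-coefficient decompositions."""
    cache = _DictCache(dict_config)
    out = []
    for qd, (nx, ny) in zip(qblocks, _block_dims(pspec)):
        My = cache.get(dspec.domain, ny).size
        pairs = [map_index_to_pair(int(o), My) for o in qd.indices]
        coeffs = np.array(
            [
                (1.0 if s == 0 else -1.0) * dequantize_magnitude(int(m), qspec)
                for m, s in zip(qd.magnitudes, qd.signs)
            ]
        )
        out.append(BlockDecomposition(pairs, coeffs, 0.0, "decoded"))
    return out


def build_code(qblocks, pspec, dspec, dict_config, qspec) -> SparseImageCode:
    """Streams plus the full self-describing header."""
    cache = _DictCache(dict_config)
    max_index = 0
    for nx, ny in set(_block_dims(pspec)):
        Mx = cache.get(dspec.domain, nx).size
        My = cache.get(dspec.domain, ny).size
        max_index = max(max_index, Mx * My)
    code = encode_streams(qblocks, pspec.n_blocks)
    cfg = dict_config or DictionaryConfig()
    code.header.update(
        {
            "delta": float(qspec.delta),
            "theta_factor": float(qspec.theta_factor),
            "original_shape": tuple(pspec.original_shape),
            "block_size": int(pspec.block_size),
            "boundary_policy": pspec.boundary_policy,
            "domain": dspec.domain,
            "wavelet_family": dspec.wavelet_family,
            "levels": int(dspec.levels),
            "index_map": "x-major",
            "dict_M": -1 if cfg.M is None else int(cfg.M),
            "dict_prototype_file": cfg.prototype_file or "",
            "dict_hash": _dict_hash(cfg),
            "max_index": int(max_index),
            "bit_depth": 8,
        }
    )
    return code


def header_specs(header: dict):
    """Rebuild the partition/domain/dictionary/quantiser specs recorded in
    a container header."""
    pspec = PartitionSpec(
        tuple(header["original_shape"]),
        int(header["block_size"]),
        str(header["boundary_policy"]),
    )
    levels = int(header["levels"])
    dspec = DomainSpec(str(header["domain"]), str(header["wavelet_family"]), levels)
    m = int(header["dict_M"])
    cfg = DictionaryConfig(
        M=None if m < 0 else m,
        prototype_file=str(header["dict_prototype_file"]) or None,
    )
    qspec = QuantizerSpec(float(header["delta"]), float(header["theta_factor"]))
    return pspec, dspec, cfg, qspec


def encode_image(
    image: np.ndarray,
    pspec: PartitionSpec,
    dspec: DomainSpec,
    dict_config: DictionaryConfig | None,
    qspec: QuantizerSpec,
    target_psnr: float = 45.0,
    psnr_margin: float = 0.75,
    approx: ApproximationResult | None = None,
) -> SparseImageCode:
    """Approximate, quantise and serialise an image at a fixed ``delta``.

    ``approx`` lets callers reuse an existing approximation (e.g. during
    rate control) instead of re-running the pursuit.
    """
    if approx is None:
        approx = approximate_image(
            image, pspec, dspec, dict_config, target_psnr, psnr_margin
        )
    qblocks = quantize_decompositions(
        approx.decompositions, pspec, dspec, dict_config, qspec
    )
    return build_code(qblocks, pspec, dspec, dict_config, qspec)


def decode_image(code: SparseImageCode, round_to_depth: bool = True) -> np.ndarray:
    """Decode a container back to an 8-bit-range image array."""
    pspec, dspec, cfg, qspec = header_specs(code.header)
    qblocks = decode_streams(code)
    decs = dequantize_decompositions(qblocks, pspec, dspec, cfg, qspec)
    recon = reconstruct_image(decs, pspec, dspec, cfg)
    peak = float(2 ** int(code.header.get("bit_depth", 8)) - 1)
    recon = np.clip(recon, 0.0, peak)
    if round_to_depth:
        recon = np.rint(recon)
    return recon


# ---------------------------------------------------------------------------
# rate control
# ---------------------------------------------------------------------------

DELTA_MIN = 1e-4
DELTA_MAX = 10.0   # initial upper bracket; grown geometrically when needed
DELTA_CAP = 1e5


@dataclass
class RateControlResult:
    delta: float
    code: SparseImageCode
    achieved_psnr: float
    target_psnr: float
    converged: bool
    iterations: int


def tune_delta(
    image: np.ndarray,
    pspec: PartitionSpec,
    dspec: DomainSpec,
    dict_config: DictionaryConfig | None,
    target_psnr: float,
    theta_factor: float = 1.3,
    psnr_margin: float = 0.75,
    tol_db: float = 0.1,
    max_iter: int = 40,
    approx: ApproximationResult | None = None,
) -> RateControlResult:
    """Bisect the quantisation step until the decoded PSNR meets the target.

    The pursuit is run once, to a slightly higher PSNR than requested;
    decoded quality is then a non-increasing function of ``delta``, and a
    bisection over ``[1e-4, 10]`` closes the loop to ``+-0.1`` dB (or 40
    iterations).  An unreachable target is reported, not raised: the result
    carries ``converged=False`` and the best achievable code (at the
    smallest step).
    """
    image = np.asarray(image, dtype=float)
    if approx is None:
        approx = approximate_image(
            image, pspec, dspec, dict_config, target_psnr, psnr_margin
        )

    def evaluate(delta: float):
        qspec = QuantizerSpec(delta, theta_factor)
        code = encode_image(
            image, pspec, dspec, dict_config, qspec, approx=approx
        )
        decoded = decode_image(code, round_to_depth=False)
        return _psnr(image, decoded), code

    lo, hi = DELTA_MIN, DELTA_MAX
    psnr_lo, code_lo = evaluate(lo)
    if psnr_lo < target_psnr - tol_db:
        return RateControlResult(lo, code_lo, psnr_lo, target_psnr, False, 1)

    best = (lo, code_lo, psnr_lo)
    iters = 1
    # a very sparse representation (few, large coefficients) may still beat
    # the target at the nominal upper bracket; widen it until straddled
    psnr_hi, code_hi = evaluate(hi)
    iters += 1
    while psnr_hi > target_psnr and hi < DELTA_CAP:
        lo, psnr_lo, code_lo = hi, psnr_hi, code_hi
        hi *= 4.0
        psnr_hi, code_hi = evaluate(hi)
        iters += 1
    if abs(psnr_hi - target_psnr) <= tol_db:
        return RateControlResult(hi, code_hi, psnr_hi, target_psnr, True, iters)
    if abs(psnr_hi - target_psnr) < abs(best[2] - target_psnr):
        best = (hi, code_hi, psnr_hi)
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection on a scale parameter
        psnr_mid, code_mid = evaluate(mid)
        iters += 1
        if abs(psnr_mid - target_psnr) <= abs(best[2] - target_psnr):
            best = (mid, code_mid, psnr_mid)
        if abs(psnr_mid - target_psnr) <= tol_db:
            return RateControlResult(mid, code_mid, psnr_mid, target_psnr, True, iters)
        if psnr_mid > target_psnr:
            lo = mid
        else:
            hi = mid
    delta, code, achieved = best
    return RateControlResult(
        delta, code, achieved, target_psnr, abs(achieved - target_psnr) <= tol_db, iters
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _smallest_uint(arr: np.ndarray):
    hi = int(arr.max(initial=0))
    for dt in (np.uint8, np.uint16, np.uint32):
        if hi <= np.iinfo(dt).max:
            return dt
    return np.uint64


def write_container(code: SparseImageCode, path, compression: int = 0) -> None:
    """Write the three streams and header to an HDF5 file.

    Streams are stored with the smallest unsigned width that holds their
    maximum; sign bits are packed eight per byte.  ``compression`` 1-9
    enables deflate (default 0: raw, matching a scheme without entropy
    coding).
    """
    kw = {"compression": "gzip", "compression_opts": compression} if compression else {}
    with h5py.File(path, "w") as f:
        g = f.create_group("streams")
        g.create_dataset("st_ind", data=code.st_ind.astype(_smallest_uint(code.st_ind)), **kw)
        g.create_dataset("st_cf", data=code.st_cf.astype(_smallest_uint(code.st_cf)), **kw)
        g.create_dataset("st_sg", data=np.packbits(code.st_sg.astype(np.uint8)), **kw)
        g["st_sg"].attrs["n_signs"] = len(code.st_sg)
        h = f.create_group("header")
        for key, val in code.header.items():
            if isinstance(val, tuple):
                val = list(val)
            h.attrs[key] = val


def read_container(path) -> SparseImageCode:
    """Read a container written by :func:`write_container`."""
    try:
        with h5py.File(path, "r") as f:
            g = f["streams"]
            n_signs = int(g["st_sg"].attrs["n_signs"])
            st_sg = np.unpackbits(g["st_sg"][...])[:n_signs]
            header = {}
            for key, val in f["header"].attrs.items():
                if isinstance(val, bytes):
                    val = val.decode()
                elif isinstance(val, np.ndarray):
                    val = tuple(int(v) for v in val)
                elif isinstance(val, np.integer):
                    val = int(val)
                elif isinstance(val, np.floating):
                    val = float(val)
                header[key] = val
            return SparseImageCode(
                g["st_ind"][...].astype(np.int64),
                g["st_cf"][...].astype(np.int64),
                st_sg.astype(np.uint8),
                header,
            )
    except (OSError, KeyError) as exc:
        raise CorruptContainerError(f"corrupt container {path}: {exc}") from exc


def payload_bits(code: SparseImageCode) -> int:
    """Size of the three streams, in bits, at their stored widths."""
    ind_bits = 8 * code.st_ind.astype(_smallest_uint(code.st_ind)).nbytes
    cf_bits = 8 * code.st_cf.astype(_smallest_uint(code.st_cf)).nbytes
    sg_bits = 8 * len(np.packbits(code.st_sg.astype(np.uint8)))
    return ind_bits + cf_bits + sg_bits


def bits_per_pixel(code: SparseImageCode) -> float:
    """Payload bits divided by the pixel count of the original image."""
    nx, ny = code.header["original_shape"]
    return payload_bits(code) / (nx * ny)
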