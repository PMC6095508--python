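"""Synthetic test images.

Two families, both fully seeded and reproducible:

* ``atoms`` phantoms — every block is an exact combination of a few
  distinct separable dictionary atoms with known coefficients, the ground
  truth returned alongside the image.  They exercise exact sparse recovery
  and make the codec testable without any external corpus.
* ``smooth`` phantoms — seeded mixtures of low-frequency 2D cosines scaled
  into the 8-bit range, with optional additive Gaussian noise.  They stand
  in for the smooth, large-scale structure of radiographs (they do not
  emulate sharp anatomical edges, film grain or annotations).

``mixed`` phantoms use atoms blocks in the top half and smooth content in
the bottom half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import PartitionSpec
from .dictionaries import DictionaryConfig, build_mixed_dictionary
from .pursuit import BlockDecomposition, reconstruct_block


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic image; identical spec and seed give a
    bitwise-identical image."""

    kind: str = "smooth"
    size: tuple = (128, 128)
    atoms_per_block: int = 5
    coefficient_range: tuple = (1.0, 2.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("atoms", "smooth", "mixed"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        lo, hi = self.coefficient_range
        if not (0 < lo <= hi):
            raise ValueError("coefficient_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_phantom(
    spec: PhantomSpec,
    dict_config: DictionaryConfig | None = None,
    block_size: int = 16,
):
    """Build a phantom image.

    Returns ``(pixels, ground_truth)`` where ``ground_truth`` is a list of
    :class:`~sparsimg.pursuit.BlockDecomposition` (one per block, row-major)
    for ``atoms`` phantoms and ``None`` otherwise.  Atom-built pixels are
    raw float combinations (not forced into the 8-bit range), since their
    purpose is exact recovery.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.size
    if spec.kind == "smooth":
        return _smooth(rng, nx, ny, spec.noise_sd), None
    if nx % block_size or ny % block_size:
        raise ValueError("atoms phantoms require dimensions divisible by block_size")
    if spec.atoms_per_block > block_size * block_size:
        raise ValueError("atoms_per_block exceeds the block pixel count")

    D = build_mixed_dictionary("pixel", block_size, dict_config)
    pspec = PartitionSpec((nx, ny), block_size)
    rows, cols = pspec.grid
    image = np.zeros((nx, ny))
    truths: list = []
    for bi, sl in enumerate(pspec.block_slices()):
        row = bi // cols
        if spec.kind == "mixed" and row >= rows // 2:
            truths.append(None)
            continue
        dec = _random_block(rng, D, spec)
        image[sl] = reconstruct_block(dec, D, D)
        truths.append(dec)
    if spec.kind == "mixed":
        half = (rows // 2) * block_size
        image[half:, :] = _smooth(rng, nx - half, ny, spec.noise_sd)
    if spec.noise_sd > 0 and spec.kind == "atoms":
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    return image, truths


def _random_block(rng, D, spec: PhantomSpec) -> BlockDecomposition:
    M = D.size
    flat = rng.choice(M * M, size=spec.atoms_per_block, replace=False)
    pairs = [(int(f) // M + 1, int(f) % M + 1) for f in flat]
    lo, hi = spec.coefficient_range
    coeffs = rng.uniform(lo, hi, spec.atoms_per_block) * rng.choice(
        [-1.0, 1.0], spec.atoms_per_block
    )
    return BlockDecomposition(pairs, coeffs, 0.0, "synthetic")


def _smooth(rng, nx: int, ny: int, noise_sd: float) -> np.ndarray:
    """Seeded low-frequency cosine mixture scaled into [20, 235]."""
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    img = np.zeros((nx, ny))
    for _ in range(6):
        fx, fy = rng.uniform(0.0, 3.0, 2)  # cycles per image side
        px, py = rng.uniform(0.0, 2 * np.pi, 2)
        amp = rng.uniform(0.5, 1.0)
        img += amp * np.cos(2 * np.pi * fx * x / max(nx, 1) + px) * np.cos(
            2 * np.pi * fy * y / max(ny, 1) + py
        )
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        img = np.full((nx, ny), 128.0)
    else:
        img = 20.0 + (img - lo) * (215.0 / (hi - lo))
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 255.0)
    return img
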