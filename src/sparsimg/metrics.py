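"""Quality and sparsity measures: PSNR, MSSIM, sparsity ratios and the
per-block digital summary map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .blocks import PartitionSpec

PEAK = 255.0


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = PEAK) -> float:
    """Peak signal-to-noise ratio in dB on the 8-bit scale,
    ``10 log10(peak^2 / MSE)``; ``inf`` when the images coincide."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("images must have the same shape")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def mssim(
    reference: np.ndarray,
    test: np.ndarray,
    win_size: int = 11,
    sigma: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
    data_range: float = PEAK,
) -> float:
    """Mean structural similarity over sliding Gaussian windows.

    Uses the standard parameters (11 x 11 Gaussian window, sigma 1.5,
    K1 = 0.01, K2 = 0.03, dynamic range 255, no pre-downsampling); equals
    1 exactly when the two images are identical.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("images must have the same shape")
    if min(reference.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}x{win_size} window")
    return float(
        structural_similarity(
            reference,
            test,
            win_size=win_size,
            gaussian_weights=True,
            sigma=sigma,
            K1=K1,
            K2=K2,
            data_range=data_range,
            use_sample_covariance=False,
        )
    )


@dataclass
class SparsityReport:
    """Global and per-block sparsity of one encoded image.

    ``sr`` is pixels over retained coefficients; ``local`` holds the
    per-block ratio ``n_pixels(q) / k_q`` (``inf`` where a block kept no
    coefficients); ``summary_map`` holds the raw ``k_q`` counts — the
    inverse local sparsity, whose rendering gives a digital summary of the
    image in which the brightest cells are the least sparse blocks.
    """

    total_pixels: int
    total_coefficients: int
    local: np.ndarray
    summary_map: np.ndarray

    @property
    def sr(self) -> float:
        if self.total_coefficients == 0:
            return float("inf")
        return self.total_pixels / self.total_coefficients


def sparsity_report(decompositions, pspec: PartitionSpec) -> SparsityReport:
    """Sparsity ratios for a list of per-block decompositions (anything
    with a ``k`` attribute, in row-major partition order)."""
    rows, cols = pspec.grid
    ks = np.array([d.k for d in decompositions], dtype=int)
    if len(ks) != rows * cols:
        raise ValueError(f"expected {rows * cols} blocks, got {len(ks)}")
    kmap = ks.reshape(rows, cols)
    sizes = np.array(
        [
            (sl[0].stop - sl[0].start) * (sl[1].stop - sl[1].start)
            for sl in pspec.block_slices()
        ]
    ).reshape(rows, cols)
    with np.errstate(divide="ignore"):
        local = np.where(kmap > 0, sizes / np.maximum(kmap, 1), np.inf)
    nx, ny = pspec.original_shape
    return SparsityReport(nx * ny, int(ks.sum()), local, kmap)


def summary_map_image(report: SparsityReport) -> np.ndarray:
    """8-bit rendering of the digital summary (k_q rescaled to 0..255)."""
    kmap = report.summary_map.astype(float)
    top = kmap.max()
    if top <= 0:
        return np.zeros(kmap.shape, dtype=np.uint8)
    return np.rint(kmap * (255.0 / top)).astype(np.uint8)


def write_summary_map(report: SparsityReport, png_path=None, text_path=None) -> None:
    """Export the digital summary as an 8-bit PNG and/or a numeric grid."""
    if png_path is not None:
        import imageio.v3 as iio

        iio.imwrite(png_path, summary_map_image(report))
    if text_path is not None:
        np.savetxt(text_path, report.summary_map, fmt="%d")
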