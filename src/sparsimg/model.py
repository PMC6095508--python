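"""High-level modelling interface.

:class:`SparseImageCoder` wraps the whole pipeline — partition, optional
wavelet transform, per-block pursuit, quantisation and stream coding — as
a model object built from an image; :meth:`SparseImageCoder.fit` returns a
:class:`SparseImageFit` results object carrying the tuned quantisation
step, quality metrics (PSNR, MSSIM), sparsity ratios before and after
quantisation, the encoded streams and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from .blocks import ApproximationResult, DomainSpec, PartitionSpec, approximate_image
from .codec import (
    QuantizerSpec,
    SparseImageCode,
    bits_per_pixel,
    decode_image,
    encode_image,
    tune_delta,
    write_container,
)
from .dictionaries import DictionaryConfig
from .imageio_utils import ImageArray, read_image
from .metrics import SparsityReport, mssim, psnr, sparsity_report


class SparseImageCoder:
    """Sparse separable-dictionary representation of one grayscale image.

    Parameters
    ----------
    image : 2D array or ImageArray
        8-bit-range grayscale intensities.
    block_size : int
        Side of the square partition blocks (16 is a good compromise
        between sparsity and processing time for radiographs).
    domain : {"pixel", "wavelet"}
        Approximate raw intensities or the wavelet coefficient array.
    wavelet, levels : str, int
        Wavelet family and decomposition depth for wavelet mode.
    boundary : {"pad-reflect", "partial-blocks"}
        Treatment of non-divisible image sizes.
    theta_factor : float
        Discard threshold as a multiple of the quantisation step.
    psnr_margin : float
        Extra dB the pursuit targets beyond the requested PSNR, headroom
        for the quality lost to quantisation.
    """

    def __init__(
        self,
        image,
        block_size: int = 16,
        domain: str = "pixel",
        wavelet: str = "bior4.4",
        levels: int = 3,
        boundary: str = "pad-reflect",
        dict_config: DictionaryConfig | None = None,
        theta_factor: float = 1.3,
        psnr_margin: float = 0.75,
    ):
        if isinstance(image, ImageArray):
            image = image.pixels
        self.image = np.asarray(image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be a 2D array")
        self.pspec = PartitionSpec(self.image.shape, block_size, boundary)
        if domain == "pixel":
            self.dspec = DomainSpec.pixel()
        else:
            self.dspec = DomainSpec.wavelet(wavelet, levels)
        self.dict_config = dict_config or DictionaryConfig()
        self.theta_factor = theta_factor
        self.psnr_margin = psnr_margin

    @classmethod
    def from_file(cls, path, **kwargs) -> "SparseImageCoder":
        return cls(read_image(path), **kwargs)

    def fit(
        self,
        target_psnr: float = 45.0,
        delta: float | None = None,
        max_atoms: int | None = None,
    ) -> "SparseImageFit":
        """Run the pursuit and close the rate-control loop.

        With ``delta`` given, quantise at that fixed step; otherwise
        bisect the step until the decoded PSNR is within 0.1 dB of
        ``target_psnr``.
        """
        approx = approximate_image(
            self.image,
            self.pspec,
            self.dspec,
            self.dict_config,
            target_psnr,
            self.psnr_margin,
            max_atoms=max_atoms,
        )
        if delta is not None:
            qspec = QuantizerSpec(delta, self.theta_factor)
            code = encode_image(
                self.image, self.pspec, self.dspec, self.dict_config, qspec,
                approx=approx,
            )
            decoded = decode_image(code, round_to_depth=False)
            achieved = psnr(self.image, decoded)
            converged = True
        else:
            rc = tune_delta(
                self.image,
                self.pspec,
                self.dspec,
                self.dict_config,
                target_psnr,
                theta_factor=self.theta_factor,
                psnr_margin=self.psnr_margin,
                approx=approx,
            )
            delta, code, achieved, converged = rc.delta, rc.code, rc.achieved_psnr, rc.converged
        return SparseImageFit(self, approx, code, float(delta), achieved, converged)


class SparseImageFit:
    """Results of fitting a :class:`SparseImageCoder`."""

    def __init__(
        self,
        model: SparseImageCoder,
        approx: ApproximationResult,
        code: SparseImageCode,
        delta: float,
        decoded_psnr: float,
        converged: bool,
    ):
        self.model = model
        self.approx = approx
        self.code = code
        self.delta = delta
        self.decoded_psnr = decoded_psnr
        self.converged = converged
        self._decoded = None

    # -- derived quantities -------------------------------------------------

    @property
    def approx_psnr(self) -> float:
        """PSNR of the unquantised approximation."""
        return self.approx.achieved_psnr

    def decoded_image(self) -> np.ndarray:
        """Decode the streams back to an 8-bit-range image."""
        if self._decoded is None:
            self._decoded = decode_image(self.code)
        return self._decoded

    @property
    def mssim(self) -> float:
        return mssim(self.model.image, self.decoded_image())

    @property
    def bpp(self) -> float:
        return bits_per_pixel(self.code)

    def sparsity_before(self) -> SparsityReport:
        """Sparsity of the raw (unquantised) decomposition."""
        return sparsity_report(self.approx.decompositions, self.model.pspec)

    def sparsity_after(self) -> SparsityReport:
        """Sparsity after quantisation dropped sub-threshold coefficients."""
        from .codec import decode_streams

        return sparsity_report(decode_streams(self.code), self.model.pspec)

    def save(self, path, compression: int = 0) -> None:
        write_container(self.code, path, compression)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted representation."""
        before = self.sparsity_before()
        after = self.sparsity_after()
        nx, ny = self.model.pspec.original_shape
        rows = [
            ("Image shape", f"{nx} x {ny}"),
            ("Domain", self.model.dspec.domain),
            ("Block size", str(self.model.pspec.block_size)),
            ("Blocks (Q)", str(self.model.pspec.n_blocks)),
            ("Approx. PSNR (dB)", f"{self.approx_psnr:.2f}"),
            ("Decoded PSNR (dB)", f"{self.decoded_psnr:.2f}"),
            ("MSSIM", f"{self.mssim:.4f}"),
            ("Delta", f"{self.delta:.6g}"),
            ("Theta", f"{self.delta * self.model.theta_factor:.6g}"),
            ("Coefficients (pre-quant)", str(before.total_coefficients)),
            ("Coefficients (stored)", str(after.total_coefficients)),
            ("SR (pre-quant)", f"{before.sr:.2f}"),
            ("SR (stored)", f"{after.sr:.2f}"),
            ("bits per pixel", f"{self.bpp:.3f}"),
            ("Rate control converged", str(self.converged)),
        ]
        width = max(len(k) for k, _ in rows) + 2
        title = "Sparse Separable-Dictionary Image Code"
        bar = "=" * (width + 22)
        lines = [title.center(len(bar)), bar]
        lines += [f"{k:<{width}}{v:>20}" for k, v in rows]
        lines.append(bar)
        return "\n".join(lines)
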