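"""Window geometry shared by tracks, model, training and inference.

All lengths are derived from five base quantities so that a miniature
geometry (used throughout the test suite) exercises exactly the same code
paths as the full-scale one.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ModelGeometry:
    """Resolutions and window lengths for one V-stripe prediction.

    The prediction window spans ``window_bp`` centered on one contact-map bin
    ``t``; the model outputs one side of the V-stripe: contacts between ``t``
    and bins at distance 0..``max_distance_bp``.
    """

    hic_resolution: int = 10_000
    acc_resolution: int = 50
    coacc_resolution: int = 500
    window_bp: int = 4_010_000
    max_distance_bp: int = 2_000_000

    def __post_init__(self) -> None:
        if self.window_bp % self.hic_resolution != 0:
            raise ValueError("window_bp must be a multiple of hic_resolution")
        if self.hic_resolution % self.acc_resolution != 0:
            raise ValueError("hic_resolution must be a multiple of acc_resolution")
        if self.hic_resolution % self.coacc_resolution != 0:
            raise ValueError("hic_resolution must be a multiple of coacc_resolution")
        if self.hic_window_bins % 2 != 1:
            raise ValueError("window must cover an odd number of contact-map bins")
        if self.window_bp != 2 * self.max_distance_bp + self.hic_resolution:
            raise ValueError(
                "window_bp must equal 2*max_distance_bp + one contact-map bin"
            )

    @property
    def hic_window_bins(self) -> int:
        """Number of contact-map bins in the window (401 at full scale)."""
        return self.window_bp // self.hic_resolution

    @property
    def acc_window_len(self) -> int:
        """Accessibility/CTCF input length L0 (80,200 at full scale)."""
        return self.window_bp // self.acc_resolution

    @property
    def coacc_window_len(self) -> int:
        """Number of co-accessibility bins in the window (8,020 at full scale)."""
        return self.window_bp // self.coacc_resolution

    @property
    def center_coacc_bins(self) -> int:
        """Co-accessibility bins inside the center contact-map bin (20)."""
        return self.hic_resolution // self.coacc_resolution

    @property
    def out_len(self) -> int:
        """One-sided stripe length including the diagonal (201 at full scale)."""
        return self.max_distance_bp // self.hic_resolution + 1

    @property
    def max_distance_bins(self) -> int:
        return self.max_distance_bp // self.hic_resolution

    @property
    def reduction_factor(self) -> int:
        """Accessibility bins per contact-map bin (200)."""
        return self.hic_resolution // self.acc_resolution

    @property
    def center_offset_bins(self) -> int:
        """Contact-map bins on each side of the window center (200)."""
        return (self.hic_window_bins - 1) // 2

    def window_start_bp(self, t: int) -> int:
        """Genomic start of the window centered on contact-map bin ``t``.

        May be negative near the chromosome start; callers zero-pad.
        """
        return (t - self.center_offset_bins) * self.hic_resolution

    @classmethod
    def default(cls) -> "ModelGeometry":
        return cls()

    @classmethod
    def mini(cls) -> "ModelGeometry":
        """Miniature geometry: 0.41Mb window, 41 contact-map bins, out_len 21."""
        return cls(window_bp=410_000, max_distance_bp=200_000)
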