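"""Spectrum quality control and reduction to bucket tables.

QC follows the standard practice for TSP-referenced extract spectra: the
0-ppm reference singlet is characterized (centering, full width at half
maximum, baseline level in signal-free regions) and spectra failing
linewidth, baseline or referencing requirements are flagged for exclusion.
Bucketing integrates each spectrum over a list of ppm intervals with the
trapezoidal rule, which is independent of the digital resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Bucket, BucketTable, Spectrum

__all__ = [
    "QCThresholds",
    "QCResult",
    "tsp_linewidth",
    "baseline_ratio",
    "qc_filter",
    "bucket_spectra",
    "read_spectrum",
    "write_spectrum",
    "write_qc_report",
]

logger = logging.getLogger(__name__)

DEFAULT_TSP_WINDOW = (-0.05, 0.05)
DEFAULT_QUIET_REGIONS = ((9.8, 10.0), (-0.3, -0.2))


@dataclass(frozen=True)
class QCThresholds:
    """QC acceptance thresholds.

    Defaults are typical for 600 MHz cryoprobe extract spectra: TSP FWHM at
    most 1.5 Hz, baseline-to-TSP ratio at most 0.01, reference centering
    within 0.005 ppm of 0.  All overridable.
    """

    max_linewidth_hz: float = 1.5
    max_baseline_ratio: float = 0.01
    center_tolerance_ppm: float = 0.005
    noise_floor: float = 0.0


@dataclass
class QCResult:
    sample_id: str
    tsp_linewidth_hz: float
    tsp_center_ppm: float
    baseline_ratio: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def _window_slice(spectrum: Spectrum, lo: float, hi: float) -> np.ndarray:
    return (spectrum.ppm >= lo) & (spectrum.ppm <= hi)


def tsp_linewidth(
    spectrum: Spectrum,
    search_window: tuple[float, float] = DEFAULT_TSP_WINDOW,
    noise_floor: float = 0.0,
) -> tuple[float, float]:
    """Locate the TSP reference peak and measure its FWHM.

    The apex is the maximum intensity inside ``search_window`` (ppm).  The
    full width at half maximum is found by linear interpolation of the two
    half-maximum crossings flanking the apex, converted to Hz through the
    spectrometer frequency.

    Returns
    -------
    (center_ppm, fwhm_hz)
    """
    lo, hi = min(search_window), max(search_window)
    mask = _window_slice(spectrum, lo, hi)
    if mask.sum() < 5:
        raise ValueError("TSP search window contains fewer than 5 points")
    ppm = spectrum.ppm[mask]
    inten = spectrum.intensity[mask]
    apex = int(np.argmax(inten))
    height = inten[apex]
    if height <= noise_floor:
        raise ValueError("TSP peak not found")
    half = height / 2.0

    def _cross(direction: int) -> float:
        i = apex
        while 0 <= i + direction < len(inten) and inten[i + direction] > half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(inten):
            raise ValueError("TSP peak not found")  # half-max never reached in window
        # linear interpolation between points i (above half) and j (below)
        f = (inten[i] - half) / (inten[i] - inten[j])
        return ppm[i] + f * (ppm[j] - ppm[i])

    left = _cross(-1)   # toward higher ppm (descending axis: lower index)
    right = _cross(+1)
    fwhm_ppm = abs(left - right)
    return float(ppm[apex]), float(fwhm_ppm * spectrum.spectrometer_freq)


def baseline_ratio(
    spectrum: Spectrum,
    quiet_regions: Sequence[tuple[float, float]] = DEFAULT_QUIET_REGIONS,
    tsp_window: tuple[float, float] = DEFAULT_TSP_WINDOW,
) -> float:
    """Mean absolute intensity in signal-free regions relative to the TSP apex.

    A well-corrected baseline gives a value near 0; broad baseline roll or
    residual macromolecule signal inflates it.
    """
    mask = np.zeros_like(spectrum.ppm, dtype=bool)
    for lo, hi in quiet_regions:
        lo, hi = min(lo, hi), max(lo, hi)
        mask |= _window_slice(spectrum, lo, hi)
    if mask.sum() < 10:
        raise ValueError("quiet regions contain fewer than 10 points")
    tsp_mask = _window_slice(spectrum, *sorted(tsp_window))
    if not tsp_mask.any():
        raise ValueError("TSP window outside spectral range")
    tsp_height = float(spectrum.intensity[tsp_mask].max())
    if tsp_height <= 0:
        raise ValueError("TSP peak not found")
    return float(np.mean(np.abs(spectrum.intensity[mask])) / tsp_height)


def qc_filter(
    spectra: Sequence[Spectrum],
    thresholds: QCThresholds = QCThresholds(),
    quiet_regions: Sequence[tuple[float, float]] = DEFAULT_QUIET_REGIONS,
    tsp_window: tuple[float, float] = DEFAULT_TSP_WINDOW,
) -> list[QCResult]:
    """Characterize the TSP reference peak of every spectrum and flag failures.

    Measurement errors (e.g. no detectable TSP peak) are reported as failed
    QC with an explanatory reason rather than raised.
    """
    results = []
    for sp in spectra:
        reasons: list[str] = []
        center = np.nan
        fwhm = np.nan
        ratio = np.nan
        try:
            center, fwhm = tsp_linewidth(sp, tsp_window, thresholds.noise_floor)
        except ValueError as exc:
            reasons.append(str(exc))
        try:
            ratio = baseline_ratio(sp, quiet_regions, tsp_window)
        except ValueError as exc:
            reasons.append(f"baseline: {exc}")
        if np.isfinite(fwhm) and fwhm > thresholds.max_linewidth_hz:
            reasons.append(
                f"linewidth {fwhm:.3g} Hz exceeds {thresholds.max_linewidth_hz} Hz"
            )
        if np.isfinite(ratio) and ratio > thresholds.max_baseline_ratio:
            reasons.append(
                f"baseline ratio {ratio:.3g} exceeds {thresholds.max_baseline_ratio}"
            )
        if np.isfinite(center) and abs(center) > thresholds.center_tolerance_ppm:
            reasons.append(
                f"reference offset {center:.4g} ppm exceeds "
                f"{thresholds.center_tolerance_ppm} ppm"
            )
        results.append(
            QCResult(
                sample_id=sp.sample_id,
                tsp_linewidth_hz=float(fwhm),
                tsp_center_ppm=float(center),
                baseline_ratio=float(ratio),
                passed=not reasons,
                reasons=reasons,
            )
        )
    return results


def bucket_spectra(spectra: Sequence[Spectrum], buckets: Sequence[Bucket]) -> BucketTable:
    """Reduce spectra to a bucket table by trapezoidal integration.

    ``value(sample, bucket)`` is the integral of intensity over the bucket's
    ppm interval.  Negative integrals (over-corrected baseline) are clipped
    to zero with a logged warning.
    """
    if not buckets:
        raise ValueError("bucket list is empty")
    if not spectra:
        raise ValueError("no spectra to bucket")
    values = np.zeros((len(spectra), len(buckets)))
    n_clipped = 0
    for i, sp in enumerate(spectra):
        ppm_min, ppm_max = sp.ppm.min(), sp.ppm.max()
        # ascending view for integration
        asc_ppm = sp.ppm[::-1]
        asc_int = sp.intensity[::-1]
        for j, b in enumerate(buckets):
            if b.ppm_right < ppm_min or b.ppm_left > ppm_max:
                raise ValueError(
                    f"bucket {b.bucket_id!r} [{b.ppm_left}, {b.ppm_right}] outside "
                    f"spectral range [{ppm_max}, {ppm_min}] of sample {sp.sample_id!r}"
                )
            lo, hi = b.ppm_right, b.ppm_left
            sel = (asc_ppm >= lo) & (asc_ppm <= hi)
            if sel.sum() < 2:
                raise ValueError(
                    f"bucket {b.bucket_id!r} covers fewer than 2 points of "
                    f"sample {sp.sample_id!r}"
                )
            v = float(np.trapezoid(asc_int[sel], asc_ppm[sel]))
            if v < 0:
                n_clipped += 1
                v = 0.0
            values[i, j] = v
    if n_clipped:
        logger.warning("clipped %d negative bucket integrals to zero", n_clipped)
    return BucketTable([sp.sample_id for sp in spectra], list(buckets), values)


# ---------------------------------------------------------------------------
# plain-text spectrum IO
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column (ppm, intensity) text with a header line carrying the
    spectrometer frequency and sample ID."""
    path = Path(path)
    lines = [f"# freq_mhz={float(spectrum.spectrometer_freq)!r} sample={spectrum.sample_id}"]
    for p, v in zip(spectrum.ppm, spectrum.intensity):
        lines.append(f"{float(p)!r}\t{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# freq_mhz=... sample=...' header")
        tokens = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        if "freq_mhz" not in tokens or "sample" not in tokens:
            raise ValueError(f"{path}: header must carry freq_mhz and sample")
        data = np.loadtxt(fh)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(
        sample_id=tokens["sample"],
        ppm=data[:, 0],
        intensity=data[:, 1],
        spectrometer_freq=float(tokens["freq_mhz"]),
    )


def write_qc_report(results: Sequence[QCResult], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "linewidth_hz": [r.tsp_linewidth_hz for r in results],
            "center_ppm": [r.tsp_center_ppm for r in results],
            "baseline_ratio": [r.baseline_ratio for r in results],
            "passed": [r.passed for r in results],
            "reasons": ["; ".join(r.reasons) for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
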