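"""Three-evidence "snake venomics" relative quantification.

Whole-venom composition is estimated by a three-step partition of 100% of
the venom:

1. RP-HPLC peak integrals at 214 nm give each collected fraction's share
   of the venom (trapezoidal integration above a baseline);
2. SDS-PAGE densitometry splits each fraction's share across its gel
   bands;
3. top3 ion intensities (summed intensity of a protein's three most
   intense peptides) split each band's share across the protein families
   identified in it.

Each step is a partition of the previous one, so mass is conserved from
chromatogram to final composition; fractions flagged as peptides are
pooled into a ``peptides`` bucket and unassigned material into
``unknown``. Family names use the standard viper-venom vocabulary (svMP
subclasses, svSP, PLA2, CTL, DI, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAMILIES",
    "Chromatogram",
    "PeakFraction",
    "GelBand",
    "BandAssignment",
    "VenomComposition",
    "DegenerateBandError",
    "integrate_fractions",
    "band_split",
    "top3_split",
    "compose",
    "suggest_boundaries",
]

#: Controlled vocabulary of toxin families (plus the two bookkeeping buckets).
FAMILIES = (
    "svMP_PI", "svMP_PIII", "DC", "PLA2", "svSP", "CTL", "DI", "LAAO",
    "CRISP", "VEGF", "KUN", "NGF", "PDE", "5N", "NP", "peptides", "unknown",
)

#: Families whose sum is conventionally reported as the svMP umbrella.
SVMP_UMBRELLA = ("svMP_PI", "svMP_PIII", "DC")


class DegenerateBandError(ValueError):
    """A band whose top3 intensities are all zero cannot be split."""


@dataclass
class Chromatogram:
    """A 214 nm absorbance trace: time in minutes, absorbance in mAU."""

    time: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape or self.time.ndim != 1:
            raise ValueError("time and absorbance must be equal-length 1-D series")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")


@dataclass
class PeakFraction:
    id: str
    start: float
    end: float
    integral: float
    area_fraction: float = 0.0


@dataclass(frozen=True)
class GelBand:
    fraction_id: str
    band_id: str
    share: float  # densitometric share within the fraction

    def __post_init__(self) -> None:
        if not 0 <= self.share <= 1:
            raise ValueError("band shares must lie in [0, 1]")


@dataclass
class BandAssignment:
    """Protein families identified in one band with their top3 intensities."""

    band_id: str
    families: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError(f"band {self.band_id!r} has no family assignment")
        for fam, inten in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown toxin family {fam!r}")
            if inten < 0:
                raise ValueError("top3 intensities must be >= 0")


@dataclass
class VenomComposition:
    """Toxin-family percentages of whole venom, summing to 100."""

    percent: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, p in self.percent.items():
            if fam not in FAMILIES:
                raise ValueError(f"unknown toxin family {fam!r}")
            if p < -1e-9:
                raise ValueError("percentages must be >= 0")
        total = sum(self.percent.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"composition sums to {total:.4f}, not 100")

    def svmp_total(self) -> float:
        """svMP umbrella: P-I + P-III + DC, the field's dual reporting."""
        return sum(self.percent.get(f, 0.0) for f in SVMP_UMBRELLA)

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {f: round(p, ndigits) for f, p in self.percent.items()}


def _baseline(c: Chromatogram, t: np.ndarray, a: np.ndarray, method: str):
    if method == "none":
        return np.zeros_like(a)
    if method == "linear":
        # straight line between the boundary absorbances of the window
        return np.interp(t, [t[0], t[-1]], [a[0], a[-1]])
    if method == "rolling_min":
        win = max(3, len(c.time) // 50)
        pad = np.pad(c.absorbance, win, mode="edge")
        roll = np.array([
            pad[i:i + 2 * win + 1].min() for i in range(len(c.absorbance))
        ])
        return np.interp(t, c.time, roll)
    raise ValueError(f"unknown baseline method {method!r}")


def integrate_fractions(c: Chromatogram, boundaries, baseline: str = "linear",
                        ids=None) -> list[PeakFraction]:
    """Integrate fraction windows of a chromatogram and normalize.

    ``boundaries`` is a list of (start, end) time windows; they must be
    non-overlapping and inside the trace. The integral is trapezoidal,
    above the chosen baseline ('linear' between window-edge absorbances,
    'none', or 'rolling_min'); negative net areas clip to zero. Relative
    areas are normalized over the supplied windows.
    """
    bounds = sorted((float(s), float(e)) for s, e in boundaries)
    if not bounds:
        raise ValueError("at least one fraction window is required")
    t0, t1 = c.time[0], c.time[-1]
    prev_end = -np.inf
    for s, e in bounds:
        if e <= s:
            raise ValueError(f"empty or inverted window ({s}, {e})")
        if s < t0 - 1e-9 or e > t1 + 1e-9:
            raise ValueError(f"window ({s}, {e}) outside the trace [{t0}, {t1}]")
        if s < prev_end - 1e-9:
            raise ValueError("fraction windows overlap")
        prev_end = e
    if ids is None:
        ids = [f"F{i + 1}" for i in range(len(bounds))]

    fractions = []
    for fid, (s, e) in zip(ids, bounds, strict=True):
        inside = (c.time > s) & (c.time < e)
        t = np.concatenate(([s], c.time[inside], [e]))
        a = np.interp(t, c.time, c.absorbance)
        area = float(np.trapezoid(a - _baseline(c, t, a, baseline), t))
        fractions.append(PeakFraction(fid, s, e, max(area, 0.0)))
    total = sum(f.integral for f in fractions)
    if total <= 0:
        raise ValueError("no net area above baseline in any fraction")
    for f in fractions:
        f.area_fraction = f.integral / total
    return fractions


def suggest_boundaries(c: Chromatogram, height_frac: float = 0.05,
                       min_prominence: float = 0.0) -> list[float]:
    """Suggest valley-to-valley cut points at local minima below a
    height threshold (fraction of the maximal absorbance)."""
    a = c.absorbance
    thr = a.min() + height_frac * (a.max() - a.min())
    cuts = [float(c.time[i]) for i in range(1, len(a) - 1)
            if a[i] <= a[i - 1] and a[i] <= a[i + 1] and a[i] <= thr
            and (a[i - 1] - a[i]) + (a[i + 1] - a[i]) >= min_prominence]
    return cuts


def band_split(fraction: PeakFraction, bands: list[GelBand],
               tol: float = 1e-6) -> dict[str, float]:
    """Split a fraction's venom share across its gel bands."""
    for b in bands:
        if b.fraction_id != fraction.id:
            raise ValueError(
                f"band {b.band_id!r} belongs to fraction {b.fraction_id!r}, "
                f"not {fraction.id!r}"
            )
    total = sum(b.share for b in bands)
    if abs(total - 1.0) > tol:
        raise ValueError(
            f"densitometric shares of fraction {fraction.id!r} sum to "
            f"{total:.6f}, not 1"
        )
    return {b.band_id: fraction.area_fraction * b.share for b in bands}


def top3_split(band_fraction: float, assignment: BandAssignment
               ) -> dict[str, float]:
    """Split a band's venom share across families by top3 intensity."""
    total = sum(i for _f, i in assignment.families)
    if total <= 0:
        raise DegenerateBandError(
            f"band {assignment.band_id!r} has no positive top3 intensity"
        )
    out: dict[str, float] = {}
    for fam, inten in assignment.families:
        out[fam] = out.get(fam, 0.0) + band_fraction * inten / total
    return out


def compose(fractions: list[PeakFraction], bands: list[GelBand],
            assignments: list[BandAssignment],
            peptide_fraction_ids=(), unassigned_policy: str = "unknown"
            ) -> VenomComposition:
    """Combine the three evidence layers into a venom composition.

    Every fraction must either carry gel bands, be flagged as a peptide
    fraction, or fall into the ``unknown`` bucket; a fraction that is both
    flagged and banded is a double assignment and rejected. Bands whose
    assignment is missing — or degenerate (all-zero top3) — are routed to
    ``unknown`` as well.
    """
    if unassigned_policy != "unknown":
        raise ValueError("only the 'unknown' unassigned policy is defined")
    peptide_ids = set(peptide_fraction_ids)
    by_fraction: dict[str, list[GelBand]] = {}
    for b in bands:
        by_fraction.setdefault(b.fraction_id, []).append(b)
    assign_by_band = {}
    for a in assignments:
        if a.band_id in assign_by_band:
            raise ValueError(f"band {a.band_id!r} assigned twice")
        assign_by_band[a.band_id] = a

    shares: dict[str, float] = {}

    def add(fam: str, v: float) -> None:
        shares[fam] = shares.get(fam, 0.0) + v

    for f in fractions:
        fb = by_fraction.get(f.id, [])
        if f.id in peptide_ids:
            if fb:
                raise ValueError(
                    f"fraction {f.id!r} is flagged peptide but also has bands"
                )
            add("peptides", f.area_fraction)
            continue
        if not fb:
            add("unknown", f.area_fraction)
            continue
        for band_id, band_share in band_split(f, fb).items():
            a = assign_by_band.get(band_id)
            if a is None:
                add("unknown", band_share)
                continue
            try:
                for fam, v in top3_split(band_share, a).items():
                    add(fam, v)
            except DegenerateBandError:
                add("unknown", band_share)

    return VenomComposition({f: 100.0 * v for f, v in shares.items()})
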