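"""Synthetic inputs with known ground truth for every analysis layer.

The generators emulate the four input kinds of a venomics workflow —
214 nm chromatograms (sums of Gaussian peaks), deconvoluted intact-mass
lists with planted glycoform ladders and reduced/nonreduced disulfide
pairs, singly charged peptide MS/MS spectra (b/y ladders plus uniform
decoy peaks), and full synthetic venoms (chromatogram + gel-band table +
top3 table rendered from a known composition). Every generator returns
its ground truth alongside the data and is fully determined by its seed.

Noise models are deliberately simple: Gaussian mass error, white
absorbance noise and uniform decoy m/z. They support controlled testing
of the inference code, not instrument realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intact import (DISULFIDE_STEP_MONO, GLYCAN_STEPS, DeconMassList,
                     MassEntry)
from .masses import Peptide, fragment_ladder
from .quant import FAMILIES, BandAssignment, Chromatogram, GelBand

__all__ = [
    "GaussianPeak",
    "SynthSpec",
    "gen_chromatogram",
    "gen_masslist",
    "gen_msms",
    "gen_venom",
    "SyntheticVenom",
]


@dataclass(frozen=True)
class GaussianPeak:
    center: float  # min
    width: float   # Gaussian sigma, min
    height: float  # mAU

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak widths must be positive")
        if self.height < 0:
            raise ValueError("peak heights must be >= 0")

    @property
    def area(self) -> float:
        """Closed-form area height * width * sqrt(2*pi)."""
        return self.height * self.width * np.sqrt(2.0 * np.pi)


@dataclass
class SynthSpec:
    """Knobs of the synthetic generators; the seed fixes all randomness."""

    seed: int = 0
    peaks: list[GaussianPeak] = field(default_factory=list)
    noise_sd: float = 0.0           # white absorbance noise, mAU
    time_range: tuple[float, float] = (0.0, 70.0)
    dt: float = 0.02                # min per sample
    mass_noise_sd: float = 0.0      # Da
    ladder_specs: list[tuple[float, list[str]]] = field(default_factory=list)
    disulfide_pairs: list[tuple[float, int]] = field(default_factory=list)
    extra_masses: list[float] = field(default_factory=list)


def gen_chromatogram(spec: SynthSpec) -> tuple[Chromatogram, list[float]]:
    """Sum-of-Gaussians chromatogram plus the analytic true areas."""
    if not spec.peaks:
        raise ValueError("need at least one peak")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.time_range[0], spec.time_range[1] + spec.dt / 2, spec.dt)
    a = np.zeros_like(t)
    for p in spec.peaks:
        a += p.height * np.exp(-0.5 * ((t - p.center) / p.width) ** 2)
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return Chromatogram(t, a), [p.area for p in spec.peaks]


def gen_masslist(spec: SynthSpec, mode: str = "mono"
                 ) -> tuple[DeconMassList, DeconMassList, dict]:
    """Mass lists with planted ladders and disulfide pairs.

    Returns (nonreduced list, reduced list, truth). Ladder members sit at
    exact registered glycan steps from their base mass, disulfide pairs at
    n * 2.01565 Da across conditions; every mass then receives independent
    Gaussian noise of sd ``mass_noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"ladders": [], "disulfides": []}
    nonred: list[MassEntry] = []
    red: list[MassEntry] = []

    def noisy(m: float) -> float:
        return m + (rng.normal(0.0, spec.mass_noise_sd) if spec.mass_noise_sd > 0 else 0.0)

    for base, steps in spec.ladder_specs:
        if base <= 0:
            raise ValueError("ladder base masses must be positive")
        masses = [base]
        for s in steps:
            masses.append(masses[-1] + GLYCAN_STEPS[s].delta(mode))
        idx = []
        for m in masses:
            idx.append(len(nonred))
            nonred.append(MassEntry(noisy(m), intensity=float(rng.uniform(1, 10)),
                                    mode=mode, condition="nonreduced"))
        truth["ladders"].append({"base": base, "steps": list(steps), "indices": idx})

    for m0, n in spec.disulfide_pairs:
        i = len(nonred)
        nonred.append(MassEntry(noisy(m0), mode=mode, condition="nonreduced"))
        j = len(red)
        red.append(MassEntry(noisy(m0 + n * DISULFIDE_STEP_MONO), mode=mode,
                             condition="reduced"))
        truth["disulfides"].append({"nonreduced_index": i, "reduced_index": j,
                                    "mass": m0, "n_bridges": n})

    for m in spec.extra_masses:
        nonred.append(MassEntry(noisy(m), mode=mode, condition="nonreduced"))

    return DeconMassList(nonred), DeconMassList(red), truth


def gen_msms(peptide: "Peptide | str", n_decoys: int = 0, seed: int = 0,
             mz_range: tuple[float, float] = (150.0, 1500.0),
             guard_ppm: float = 20.0) -> tuple[np.ndarray, dict]:
    """Simulated singly charged spectrum: full b/y ladder plus decoys.

    Decoy peaks are uniform in ``mz_range`` but rejected within
    ``guard_ppm`` of any true peak, so the planted annotation stays
    unambiguous. Returns (sorted m/z array, truth dict with the b and y
    ladders and the generating sequence).
    """
    p = peptide if isinstance(peptide, Peptide) else Peptide.parse(peptide)
    rng = np.random.default_rng(seed)
    b = fragment_ladder(p, "b")
    y = fragment_ladder(p, "y")
    true_peaks = sorted(b + y)
    decoys: list[float] = []
    while len(decoys) < n_decoys:
        m = float(rng.uniform(*mz_range))
        if all(abs(m - t) / t * 1e6 > guard_ppm for t in true_peaks):
            decoys.append(m)
    peaks = np.array(sorted(true_peaks + decoys))
    truth = {"sequence": p.render(), "b": b, "y": y}
    return peaks, truth


@dataclass
class SyntheticVenom:
    """A rendered synthetic venom and its generating ground truth."""

    chromatogram: Chromatogram
    boundaries: list[tuple[float, float]]
    fraction_ids: list[str]
    bands: list[GelBand]
    assignments: list[BandAssignment]
    peptide_fraction_ids: list[str]
    true_composition: dict[str, float]  # family -> percent


def gen_venom(seed: int = 0, n_fractions: int = 7, n_bands: int = 12,
              n_families: int = 8, noise_sd: float = 0.0) -> SyntheticVenom:
    """Draw a random venom composition and render it into pipeline inputs.

    The default scale (7 fractions, 12 bands, 8 protein families plus a
    peptide fraction) is roughly that of one viper venom proteome. The
    composition is drawn from a flat Dirichlet; one fraction is the
    peptide fraction, the remaining protein mass is distributed over bands
    (one or two families per band with random top3 intensities) and bands
    over fractions, then everything is rendered as Gaussian peaks whose
    analytic areas equal the fraction shares.
    """
    if n_bands < n_fractions - 1:
        raise ValueError("need at least one band per protein fraction")
    rng = np.random.default_rng(seed)
    protein_fams = [f for f in FAMILIES if f not in ("peptides", "unknown")]
    fams = list(rng.choice(protein_fams, size=n_families, replace=False))

    w = rng.dirichlet(np.ones(n_families + 1))  # families + peptides
    peptide_share = float(w[-1])
    fam_share = dict(zip(fams, map(float, w[:-1])))

    # allocate each family's mass across 1-3 owning bands
    n_protein_fractions = n_fractions - 1
    band_fraction_idx = [i % n_protein_fractions for i in range(n_bands)]
    band_family_mass: list[dict[str, float]] = [dict() for _ in range(n_bands)]
    for fam, share in fam_share.items():
        owners = rng.choice(n_bands, size=int(rng.integers(1, 3)), replace=False)
        parts = rng.dirichlet(np.ones(len(owners)))
        for b, part in zip(owners, parts):
            d = band_family_mass[int(b)]
            d[fam] = d.get(fam, 0.0) + share * float(part)

    band_mass = [sum(d.values()) for d in band_family_mass]
    frac_mass = [0.0] * n_protein_fractions
    for b, fi in enumerate(band_fraction_idx):
        frac_mass[fi] += band_mass[b]

    # fractions with zero protein mass would break densitometric shares:
    # donate a nonzero band from a fraction that can spare one
    for fi in range(n_protein_fractions):
        if frac_mass[fi] > 0:
            continue
        donors = sorted(
            (b for b in range(n_bands)
             if band_mass[b] > 0
             and sum(1 for bb in range(n_bands)
                     if band_fraction_idx[bb] == band_fraction_idx[b]
                     and band_mass[bb] > 0) > 1),
            key=lambda b: band_mass[b],
        )
        if not donors:
            continue  # degenerate draw; fraction falls into 'unknown'
        b = donors[-1]
        frac_mass[band_fraction_idx[b]] -= band_mass[b]
        band_fraction_idx[b] = fi
        frac_mass[fi] += band_mass[b]

    fraction_ids = [f"F{i + 1}" for i in range(n_fractions)]
    peptide_fid = fraction_ids[-1]

    bands: list[GelBand] = []
    assignments: list[BandAssignment] = []
    for b, d in enumerate(band_family_mass):
        if band_mass[b] <= 0:
            continue
        fid = fraction_ids[band_fraction_idx[b]]
        share = min(1.0, band_mass[b] / frac_mass[band_fraction_idx[b]])
        bands.append(GelBand(fid, f"B{b + 1}", share))
        scale = float(rng.uniform(1e8, 1e10))
        assignments.append(BandAssignment(
            f"B{b + 1}", [(fam, v * scale) for fam, v in d.items()]
        ))

    # render chromatogram: one Gaussian per fraction, area == share
    shares = frac_mass + [peptide_share]
    centers = np.linspace(8.0, 62.0, n_fractions)
    sigma = 0.6
    peaks = [GaussianPeak(float(c), sigma, s / (sigma * np.sqrt(2 * np.pi)))
             for c, s in zip(centers, shares)]
    chrom, _areas = gen_chromatogram(SynthSpec(seed=seed, peaks=peaks,
                                               noise_sd=noise_sd))
    boundaries = [(float(c - 4 * sigma), float(c + 4 * sigma)) for c in centers]

    truth = {fam: 100.0 * s for fam, s in fam_share.items()}
    truth["peptides"] = 100.0 * peptide_share
    return SyntheticVenom(
        chromatogram=chrom,
        boundaries=boundaries,
        fraction_ids=fraction_ids,
        bands=bands,
        assignments=assignments,
        peptide_fraction_ids=[peptide_fid],
        true_composition=truth,
    )
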