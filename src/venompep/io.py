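"""Table dialects and configuration.

One place for every file format the package reads or writes:

* peptide tables (TSV): ``section, sequence, mono_mh, z2_mz, <venom
  presence flags>, notes`` — the dialect of published viper peptidome
  tables, with ``pE`` and ``_ox_``-style markers in the sequence column;
* deconvoluted mass lists (CSV): ``mass, intensity, mode, condition,
  label``;
* chromatograms (CSV): ``time_min, mAU``; fraction boundaries (CSV):
  ``id, start_min, end_min``;
* gel bands (TSV): ``fraction, band, share``; band assignments (TSV):
  ``band, family, top3``;
* venom compositions (CSV or JSON, sorted keys, lossless round trip).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import masses
from .intact import DeconMassList, MassEntry
from .quant import BandAssignment, Chromatogram, GelBand, VenomComposition

__all__ = [
    "Config",
    "DEFAULT_CONFIG",
    "PeptideTableRow",
    "read_peptide_table",
    "load_reference_peptides",
    "read_masslist",
    "write_masslist",
    "read_chromatogram",
    "write_chromatogram",
    "read_boundaries",
    "write_boundaries",
    "read_bands",
    "write_bands",
    "read_assignments",
    "write_assignments",
    "read_composition",
    "write_composition",
]

#: Tolerance for validating a table's stored MH+ against recomputation (Da).
MH_VALIDATION_TOL = 0.005


@dataclass(frozen=True)
class Config:
    """Physical constants and default tolerances, serializable as a dict."""

    proton_mass: float = masses.PROTON_MASS
    water_mono: float = masses.WATER_MONO
    water_avg: float = masses.WATER_AVG
    disulfide_step_mono: float = 2.01565
    disulfide_step_avg: float = 2.01588
    ppm_tol: float = 10.0
    mono_da_tol: float = 0.05
    avg_da_tol: float = 0.5
    display_decimals: int = 3

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        return cls(**d)


DEFAULT_CONFIG = Config()


@dataclass
class PeptideTableRow:
    """One row of a peptide table with its validation state.

    ``mass_flag`` is set (not dropped) when the stored MH+ deviates from
    the recomputed value by more than 0.005 Da.
    """

    sequence: str
    mono_mh: float | None = None
    z2_mz: float | None = None
    section: str = ""
    presence: dict[str, bool] = field(default_factory=dict)
    notes: str = ""
    recomputed_mh: float | None = None
    mass_flag: bool = False
    parse_error: str | None = None


_META_COLS = {"section", "sequence", "mono_mh", "z2_mz", "notes"}


def read_peptide_table(path) -> list[PeptideTableRow]:
    """Read a peptide table TSV and validate stored masses.

    Any column other than the known meta columns is treated as a venom
    presence flag (truthy for a non-empty cell). Rows whose sequence does
    not parse carry ``parse_error`` instead of raising, so a single bad
    row does not lose the table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: peptide tables need a 'sequence' column")
    rows: list[PeptideTableRow] = []
    flag_cols = [c for c in df.columns if c not in _META_COLS]
    for lineno, rec in enumerate(df.to_dict("records"), start=2):
        seq = rec["sequence"].strip()
        if not seq:
            raise ValueError(f"{path}:{lineno}: empty sequence")
        row = PeptideTableRow(
            sequence=seq,
            mono_mh=float(rec["mono_mh"]) if rec.get("mono_mh", "") else None,
            z2_mz=float(rec["z2_mz"]) if rec.get("z2_mz", "") else None,
            section=rec.get("section", ""),
            notes=rec.get("notes", ""),
            presence={c: bool(rec[c].strip()) for c in flag_cols},
        )
        try:
            m = masses.neutral_mass(seq)
            row.recomputed_mh = masses.mz(m, 1)
            if row.mono_mh is not None and abs(row.recomputed_mh - row.mono_mh) > MH_VALIDATION_TOL:
                row.mass_flag = True
        except masses.PeptideParseError as exc:
            row.parse_error = f"line {lineno}: {exc}"
        rows.append(row)
    return rows


def load_reference_peptides() -> list[PeptideTableRow]:
    """The packaged reference table of svMP-i/BPP/NP peptides observed
    across seven Palearctic viper venoms."""
    ref = resources.files("venompep").joinpath("data/viper_peptides.tsv")
    with resources.as_file(ref) as path:
        return read_peptide_table(path)


def read_masslist(path) -> DeconMassList:
    df = pd.read_csv(path)
    entries = [
        MassEntry(
            mass=float(r["mass"]),
            intensity=float(r.get("intensity", 1.0) or 1.0),
            mode=str(r.get("mode", "avg") or "avg"),
            condition=str(r.get("condition", "nonreduced") or "nonreduced"),
            label=str(r.get("label", "") or ""),
        )
        for r in df.to_dict("records")
    ]
    return DeconMassList(entries)


def write_masslist(ml: DeconMassList, path) -> None:
    pd.DataFrame([asdict(e) for e in ml.entries]).to_csv(path, index=False)


def read_chromatogram(path) -> Chromatogram:
    df = pd.read_csv(path)
    return Chromatogram(df["time_min"].to_numpy(), df["mAU"].to_numpy())


def write_chromatogram(c: Chromatogram, path) -> None:
    pd.DataFrame({"time_min": c.time, "mAU": c.absorbance}).to_csv(path, index=False)


def read_boundaries(path) -> tuple[list[str], list[tuple[float, float]]]:
    df = pd.read_csv(path)
    return (list(df["id"].astype(str)),
            [(float(s), float(e)) for s, e in zip(df["start_min"], df["end_min"])])


def write_boundaries(ids, bounds, path) -> None:
    pd.DataFrame({
        "id": ids,
        "start_min": [b[0] for b in bounds],
        "end_min": [b[1] for b in bounds],
    }).to_csv(path, index=False)


def read_bands(path) -> list[GelBand]:
    df = pd.read_csv(path, sep="\t")
    return [GelBand(str(r["fraction"]), str(r["band"]), float(r["share"]))
            for r in df.to_dict("records")]


def write_bands(bands, path) -> None:
    pd.DataFrame([
        {"fraction": b.fraction_id, "band": b.band_id, "share": b.share}
        for b in bands
    ]).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> list[BandAssignment]:
    df = pd.read_csv(path, sep="\t")
    by_band: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    for r in df.to_dict("records"):
        b = str(r["band"])
        if b not in by_band:
            by_band[b] = []
            order.append(b)
        by_band[b].append((str(r["family"]), float(r["top3"])))
    return [BandAssignment(b, by_band[b]) for b in order]


def write_assignments(assignments, path) -> None:
    pd.DataFrame([
        {"band": a.band_id, "family": fam, "top3": inten}
        for a in assignments
        for fam, inten in a.families
    ]).to_csv(path, sep="\t", index=False)


def write_composition(vc: VenomComposition, path, fmt: str | None = None) -> None:
    """Write a composition as CSV or JSON (sorted keys, byte-stable)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        path.write_text(json.dumps(vc.percent, sort_keys=True, indent=2) + "\n")
    elif fmt == "csv":
        pd.DataFrame(
            sorted(vc.percent.items()), columns=["family", "percent"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown composition format {fmt!r}")


def read_composition(path, fmt: str | None = None) -> VenomComposition:
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        return VenomComposition(json.loads(path.read_text()))
    df = pd.read_csv(path)
    return VenomComposition(dict(zip(df["family"], df["percent"].astype(float))))
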