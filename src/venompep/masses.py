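"""Exact mass arithmetic for pyroglutamate-initiated venom peptides.

Venom peptidomes of vipers are dominated by short proline-rich peptides
(svMP inhibitors, bradykinin-potentiating peptides, natriuretic peptides)
whose N-terminus is usually blocked by pyroglutamate (pE), a cyclized
residue formed from Gln or Glu. This module computes neutral monoisotopic
and average masses of such peptides, their (multimer) charge states and
b/y fragment ladders, and matches observed against theoretical peaks.

Pyroglutamate is modelled as a first-position residue ``pE`` with elemental
formula C5H5NO2 (mono 111.03203 Da). Whether it arose from Gln (loss of
NH3) or Glu (loss of H2O) is mass-indistinguishable, so no precursor is
assumed. Leu/Ile are kept as distinct codes with identical mass; reports
flag their positions as isobaric.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "WATER_AVG",
    "ResidueMassTable",
    "Modification",
    "MODIFICATIONS",
    "Peptide",
    "IonSpec",
    "PeptideParseError",
    "neutral_mass",
    "mz",
    "multimer_ion_mz",
    "fragment_ladder",
    "match_observed",
    "MatchReport",
    "denovo_from_spectrum",
]

#: Proton mass used throughout ion m/z arithmetic (Da).
PROTON_MASS = 1.00728
#: Monoisotopic / average mass of water added for the peptide termini (Da).
WATER_MONO = 18.01056
WATER_AVG = 18.0153

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

ISOBARIC_CODES = frozenset({"I", "L"})


class PeptideParseError(ValueError):
    """A display string could not be resolved against the residue table."""


def _formula_string(comp: _pmass.Composition) -> str:
    return "".join(
        f"{el}{n}" if n != 1 else el
        for el, n in sorted(comp.items())
        if n
    )


class ResidueMassTable:
    """Residue symbols -> monoisotopic mass, average mass, elemental formula.

    Contains the 20 standard amino acids plus the compound code ``pE``
    (pyroglutamate, C5H5NO2). Extra codes may be registered with
    :meth:`register`.
    """

    def __init__(self) -> None:
        self._comp: dict[str, _pmass.Composition] = {
            aa: _pmass.Composition(_pmass.std_aa_comp[aa]) for aa in _STANDARD_AA
        }
        self._comp["pE"] = _pmass.Composition(formula="C5H5NO2")
        self._mono = {c: _pmass.calculate_mass(composition=k) for c, k in self._comp.items()}
        self._avg = {
            c: _pmass.calculate_mass(composition=k, average=True)
            for c, k in self._comp.items()
        }

    def register(self, code: str, formula: str) -> None:
        comp = _pmass.Composition(formula=formula)
        self._comp[code] = comp
        self._mono[code] = _pmass.calculate_mass(composition=comp)
        self._avg[code] = _pmass.calculate_mass(composition=comp, average=True)

    def __contains__(self, code: str) -> bool:
        return code in self._comp

    def codes(self) -> tuple[str, ...]:
        return tuple(self._comp)

    def mono(self, code: str) -> float:
        try:
            return self._mono[code]
        except KeyError:
            raise PeptideParseError(f"unknown residue code {code!r}") from None

    def avg(self, code: str) -> float:
        try:
            return self._avg[code]
        except KeyError:
            raise PeptideParseError(f"unknown residue code {code!r}") from None

    def mass(self, code: str, mode: str = "mono") -> float:
        return self.mono(code) if mode == "mono" else self.avg(code)

    def formula(self, code: str) -> str:
        return _formula_string(self._comp[code])


#: Shared default table; construction touches pyteomics only once.
DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Modification:
    """A positional mass shift with the residues/termini it may sit on.

    ``targets=None`` means the modification is residue-agnostic.
    """

    name: str
    mono_delta: float
    avg_delta: float
    targets: frozenset[str] | None = None
    marker: str = ""

    def allowed_on(self, code: str) -> bool:
        return self.targets is None or code in self.targets


def _mod(name, formula, targets, marker):
    comp = _pmass.Composition(formula=formula)
    return Modification(
        name=name,
        mono_delta=_pmass.calculate_mass(composition=comp),
        avg_delta=_pmass.calculate_mass(composition=comp, average=True),
        targets=frozenset(targets) if targets else None,
        marker=marker,
    )


#: Registry of the modifications seen in viper peptidomes: Met/Trp oxidation,
#: Trp dioxidation, carbamidomethylated Cys from tryptic digests, hydration.
MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in (
        _mod("ox", "O", "MWCHFYP", "_ox_"),
        _mod("diox", "O2", "MW", "_diox_"),
        _mod("CAM", "C2H3NO", "C", "_CAM_"),
        _mod("hydration", "H2O", None, "_h2o_"),
    )
}

#: Tolerated spelling variants of modification markers in input tables.
_MARKER_ALIASES = {
    "ox": "ox",
    "oxidation": "ox",
    "diox": "diox",
    "dioxidation": "diox",
    "cam": "CAM",
    "carbamidomethyl": "CAM",
    "h2o": "hydration",
    "hydration": "hydration",
}

_MARKER_RE = re.compile(r"_([A-Za-z0-9]+)_|\(([A-Za-z0-9]+)\)")


@dataclass(frozen=True)
class Peptide:
    """An ordered residue string with per-position modifications.

    ``residues`` holds residue codes (``pE`` counts as one residue);
    ``mods`` holds ``(position, modification name)`` pairs with 1-based
    positions. The canonical display dialect renders modifications as
    ``_ox_``-style markers immediately after their residue, e.g.
    ``pEKW_ox_`` for C-terminally oxidized Trp.
    """

    residues: tuple[str, ...]
    mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        for code in self.residues:
            if code not in DEFAULT_TABLE:
                raise PeptideParseError(f"unknown residue code {code!r}")
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.residues):
                raise PeptideParseError(
                    f"modification {name!r} at position {pos} outside peptide"
                )
            mod = MODIFICATIONS.get(name)
            if mod is None:
                raise PeptideParseError(f"unknown modification {name!r}")
            if not mod.allowed_on(self.residues[pos - 1]):
                raise PeptideParseError(
                    f"modification {name!r} not allowed on "
                    f"{self.residues[pos - 1]!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bare_sequence(self) -> str:
        """Display string with modification markers stripped."""
        return "".join(self.residues)

    def isobaric_positions(self) -> tuple[int, ...]:
        """1-based positions holding Leu/Ile, indistinguishable by mass."""
        return tuple(
            i + 1 for i, c in enumerate(self.residues) if c in ISOBARIC_CODES
        )

    def without_mods(self) -> "Peptide":
        return replace(self, mods=())

    @classmethod
    def parse(cls, text: str) -> "Peptide":
        """Parse a display string in the table dialect.

        Accepts a leading ``pE`` (or the tolerated alias ``pGlu``),
        single-letter residues and ``_ox_``/``(ox)``-style markers after a
        residue; whitespace is ignored.
        """
        s = re.sub(r"\s+", "", text)
        if not s:
            raise PeptideParseError("empty sequence")
        if s.startswith("pGlu"):
            s = "pE" + s[4:]
        residues: list[str] = []
        mods: list[tuple[int, str]] = []
        i = 0
        while i < len(s):
            if s.startswith("pE", i):
                if residues:
                    raise PeptideParseError(
                        f"pyroglutamate marker at position {len(residues) + 1}: "
                        "pE is only valid at the N-terminus"
                    )
                residues.append("pE")
                i += 2
                continue
            m = _MARKER_RE.match(s, i)
            if m:
                raw = (m.group(1) or m.group(2)).lower()
                name = _MARKER_ALIASES.get(raw)
                if name is None:
                    raise PeptideParseError(f"unknown modification marker {m.group(0)!r}")
                if not residues:
                    raise PeptideParseError(
                        f"modification marker {m.group(0)!r} before any residue"
                    )
                mods.append((len(residues), name))
                i = m.end()
                continue
            code = s[i]
            if code not in DEFAULT_TABLE:
                raise PeptideParseError(f"unknown residue code {code!r} in {text!r}")
            residues.append(code)
            i += 1
        return cls(residues=tuple(residues), mods=tuple(mods))

    def render(self) -> str:
        """Canonical display string; ``parse(render())`` round-trips."""
        by_pos: dict[int, list[str]] = {}
        for pos, name in self.mods:
            by_pos.setdefault(pos, []).append(name)
        out = []
        for i, code in enumerate(self.residues, start=1):
            out.append(code)
            for name in by_pos.get(i, ()):
                out.append(MODIFICATIONS[name].marker)
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class IonSpec:
    """Which ion of a peptide: series, fragment index, charge, multimer count.

    ``n > 1`` (noncovalent multimers such as the 2M+H species of pEKW) is
    only meaningful for the precursor series.
    """

    series: str = "precursor"  # precursor | b | y
    index: int = 0
    z: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        if self.series not in ("precursor", "b", "y"):
            raise ValueError(f"unknown ion series {self.series!r}")
        if self.z < 1:
            raise ValueError("charge z must be >= 1")
        if self.n < 1:
            raise ValueError("multimer count n must be >= 1")
        if self.n > 1 and self.series != "precursor":
            raise ValueError("multimers are only defined for the precursor series")


def _as_peptide(p: "Peptide | str") -> Peptide:
    return p if isinstance(p, Peptide) else Peptide.parse(p)


def neutral_mass(p: "Peptide | str", mode: str = "mono",
                 table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral peptide mass: residue masses + modification deltas + water."""
    if mode not in ("mono", "avg"):
        raise ValueError(f"mode must be 'mono' or 'avg', got {mode!r}")
    p = _as_peptide(p)
    total = sum(table.mass(c, mode) for c in p.residues)
    for _pos, name in p.mods:
        m = MODIFICATIONS[name]
        total += m.mono_delta if mode == "mono" else m.avg_delta
    return total + (WATER_MONO if mode == "mono" else WATER_AVG)


def mz(neutral: float, z: int) -> float:
    """m/z of the z-fold protonated species: (M + z*1.00728) / z."""
    if z < 1:
        raise ValueError("charge z must be >= 1")
    return (neutral + z * PROTON_MASS) / z


def multimer_ion_mz(p: "Peptide | str", n: int = 1, z: int = 1,
                    mode: str = "mono") -> float:
    """m/z of the nM+zH ion, e.g. the 2M+H dimer ion of pEKW at 887.441."""
    if n < 1:
        raise ValueError("multimer count n must be >= 1")
    return mz(n * neutral_mass(p, mode), z)


def fragment_ladder(p: "Peptide | str", series: str, z: int = 1,
                    mode: str = "mono",
                    table: ResidueMassTable = DEFAULT_TABLE) -> list[float]:
    """b- or y-ion m/z ladder of a peptide (len(p) - 1 entries).

    b_i covers residues 1..i (with their modifications); y_i covers the
    last i residues plus the C-terminal water. Singly charged convention:
    b_i = sum + z*1.00728 at z=1; general z divides as usual.
    """
    if series not in ("b", "y"):
        raise ValueError(f"fragment series must be 'b' or 'y', got {series!r}")
    if z < 1:
        raise ValueError("charge z must be >= 1")
    p = _as_peptide(p)
    if len(p) == 0:
        raise ValueError("empty peptide has no fragments")
    water = WATER_MONO if mode == "mono" else WATER_AVG
    mod_at = {}
    for pos, name in p.mods:
        m = MODIFICATIONS[name]
        mod_at[pos] = mod_at.get(pos, 0.0) + (m.mono_delta if mode == "mono" else m.avg_delta)
    res = [table.mass(c, mode) + mod_at.get(i + 1, 0.0) for i, c in enumerate(p.residues)]
    out: list[float] = []
    if series == "b":
        acc = 0.0
        for r in res[:-1]:
            acc += r
            out.append((acc + z * PROTON_MASS) / z)
    else:
        acc = water
        for r in reversed(res[1:]):
            acc += r
            out.append((acc + z * PROTON_MASS) / z)
    return out


@dataclass
class MatchReport:
    """Result of greedy peak matching.

    ``matches`` holds (observed, theoretical, error) triples where the error
    is in the requested unit (ppm or Da, observed minus theoretical).
    """

    matches: list[tuple[float, float, float]] = field(default_factory=list)
    unmatched_observed: list[float] = field(default_factory=list)
    unmatched_theoretical: list[float] = field(default_factory=list)
    unit: str = "ppm"

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def match_observed(observed: list[float], theoretical: list[float],
                   tol: float = 10.0, unit: str = "ppm") -> MatchReport:
    """Greedily pair observed with theoretical peaks within a tolerance.

    Candidate pairs are taken in order of increasing absolute error; each
    observed and each theoretical peak is used at most once.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if unit not in ("ppm", "Da"):
        raise ValueError("unit must be 'ppm' or 'Da'")

    def err(o: float, t: float) -> float:
        return (o - t) / t * 1e6 if unit == "ppm" else o - t

    cand = sorted(
        ((abs(err(o, t)), i, j)
         for i, o in enumerate(observed)
         for j, t in enumerate(theoretical)
         if abs(err(o, t)) <= tol),
        key=lambda c: c[0],
    )
    used_o: set[int] = set()
    used_t: set[int] = set()
    rep = MatchReport(unit=unit)
    for _e, i, j in cand:
        if i in used_o or j in used_t:
            continue
        used_o.add(i)
        used_t.add(j)
        rep.matches.append((observed[i], theoretical[j], err(observed[i], theoretical[j])))
    rep.unmatched_observed = [o for i, o in enumerate(observed) if i not in used_o]
    rep.unmatched_theoretical = [t for j, t in enumerate(theoretical) if j not in used_t]
    return rep


def denovo_from_spectrum(peaks: list[float], length: int,
                         tol_ppm: float = 10.0,
                         allow_pyroglutamate: bool = True,
                         table: ResidueMassTable = DEFAULT_TABLE) -> list[str]:
    """Exhaustively infer candidate sequences whose full singly charged
    b/y ladder is contained in ``peaks``.

    Intended for short peptides (<= 8 residues); returns bare sequences
    with Leu/Ile collapsed to ``L`` (they are isobaric and cannot be told
    apart by mass). The search walks prefix (b-ion) masses depth-first,
    then validates the complementary y ladder.
    """
    if length < 2:
        raise ValueError("need at least two residues for a fragment ladder")
    peaks = sorted(peaks)

    def present(target: float) -> bool:
        # binary search with ppm window
        lo, hi = 0, len(peaks)
        while lo < hi:
            mid = (lo + hi) // 2
            if peaks[mid] < target:
                lo = mid + 1
            else:
                hi = mid
        for k in (lo - 1, lo):
            if 0 <= k < len(peaks) and abs(peaks[k] - target) / target * 1e6 <= tol_ppm:
                return True
        return False

    codes = [c for c in table.codes() if c != "I"]  # I/L isobaric: keep L
    results: list[str] = []

    def dfs(prefix: list[str], acc: float) -> None:
        depth = len(prefix)
        if depth == length - 1:
            for last in codes:
                if last == "pE":
                    continue
                total = acc + table.mono(last)
                # validate full y ladder
                suffix = 0.0
                ok = True
                seq = prefix + [last]
                for i in range(1, length):
                    suffix += table.mono(seq[length - i])
                    if not present(suffix + WATER_MONO + PROTON_MASS):
                        ok = False
                        break
                if ok:
                    results.append("".join(seq))
            return
        for code in codes:
            if code == "pE" and (depth > 0 or not allow_pyroglutamate):
                continue
            nxt = acc + table.mono(code)
            if present(nxt + PROTON_MASS):
                dfs(prefix + [code], nxt)

    dfs([], 0.0)
    return sorted(set(results))
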