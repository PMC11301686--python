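"""Proteoform inference from deconvoluted intact-mass lists.

Top-down LC-MS of whole venom yields lists of deconvoluted neutral masses
(average or monoisotopic, from reduced or nonreduced runs). Without any
database search, a lot of proteoform structure can be read off these lists
directly:

* glycoform ladders — series of masses separated by glycan-unit steps
  (HexNAc 203.08, Hex 162.05, NeuAc 291.10 Da), typical of the heavily
  N-glycosylated venom serine proteases;
* small-shift relations — pairs separated by named chemical deltas such as
  oxidation (+15.99), CO (+27.99) or hydration (+18.01 Da), which relate
  proteoforms of one toxin across species or within a dimeric disintegrin
  swarm;
* disulfide counts — a protein with n disulfide bridges gains n * 2.01565
  Da (two hydrogens per bridge) upon reduction, so the reduced/nonreduced
  mass difference counts its bridges (e.g. a CRISP fragment at 6414.61 ->
  6424.68 Da has five).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = [
    "MassEntry",
    "DeconMassList",
    "GlycanStep",
    "GLYCAN_STEPS",
    "SHIFT_DELTAS",
    "LadderHit",
    "DisulfideEstimate",
    "ShiftRelation",
    "ConditionPair",
    "InconsistentMassesError",
    "detect_ladders",
    "count_disulfides",
    "relate_masses",
    "pair_conditions",
    "DISULFIDE_STEP_MONO",
    "DISULFIDE_STEP_AVG",
]

#: Mass gained per disulfide bridge upon reduction: two hydrogens.
DISULFIDE_STEP_MONO = 2.01565
DISULFIDE_STEP_AVG = 2.01588


class InconsistentMassesError(ValueError):
    """Reduced mass below the nonreduced mass beyond tolerance."""


@dataclass(frozen=True)
class MassEntry:
    mass: float
    intensity: float = 1.0
    mode: str = "avg"  # mono | avg
    condition: str = "nonreduced"  # reduced | nonreduced
    label: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("masses must be positive")
        if self.mode not in ("mono", "avg"):
            raise ValueError(f"mode must be 'mono' or 'avg', got {self.mode!r}")
        if self.condition not in ("reduced", "nonreduced"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class DeconMassList:
    """A deconvoluted intact-mass list (z = 1 neutral-ish masses)."""

    entries: list[MassEntry] = field(default_factory=list)

    @classmethod
    def from_masses(cls, masses, intensities=None, mode="avg",
                    condition="nonreduced") -> "DeconMassList":
        if intensities is None:
            intensities = [1.0] * len(masses)
        return cls([
            MassEntry(m, i, mode, condition)
            for m, i in zip(masses, intensities, strict=True)
        ])

    def __len__(self) -> int:
        return len(self.entries)

    def masses(self) -> list[float]:
        return [e.mass for e in self.entries]


@dataclass(frozen=True)
class GlycanStep:
    """A glycan building block observed as an intact-mass ladder step."""

    name: str
    mono_delta: float
    avg_delta: float
    symbol: str

    def delta(self, mode: str) -> float:
        return self.mono_delta if mode == "mono" else self.avg_delta


def _glycan(name, formula, symbol):
    comp = _pmass.Composition(formula=formula)
    return GlycanStep(
        name,
        _pmass.calculate_mass(composition=comp),
        _pmass.calculate_mass(composition=comp, average=True),
        symbol,
    )


#: HexNAc / Hex / NeuAc as residue (anhydro) masses, the canonical ladder steps.
GLYCAN_STEPS: dict[str, GlycanStep] = {
    g.name: g
    for g in (
        _glycan("HexNAc", "C8H13NO5", "■"),
        _glycan("Hex", "C6H10O5", "●"),
        _glycan("NeuAc", "C11H17NO8", "◆"),
    )
}


def _delta_registry():
    def d(formula):
        c = _pmass.Composition(formula=formula)
        return (_pmass.calculate_mass(composition=c),
                _pmass.calculate_mass(composition=c, average=True))

    reg = {"O": d("O"), "CO": d("CO"), "H2O": d("H2O")}
    for g in GLYCAN_STEPS.values():
        reg[g.name] = (g.mono_delta, g.avg_delta)
    return reg


#: Named proteoform shifts for relate_masses: (mono, avg) deltas in Da.
SHIFT_DELTAS: dict[str, tuple[float, float]] = _delta_registry()


@dataclass
class LadderHit:
    """A maximal chain of masses linked by registered glycan steps."""

    base_mass: float
    steps: list[str]
    members: list[int]  # indices into the source DeconMassList
    residuals: list[float]
    summed_intensity: float

    @property
    def max_residual(self) -> float:
        return max(abs(r) for r in self.residuals) if self.residuals else 0.0

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DisulfideEstimate:
    n_bridges: int
    delta_mass: float
    residual: float
    accepted: bool


@dataclass
class ShiftRelation:
    from_index: int
    to_index: int
    from_mass: float
    to_mass: float
    name: str
    residual: float


@dataclass
class ConditionPair:
    nonreduced_index: int
    reduced_index: int
    estimate: DisulfideEstimate
    ambiguous: bool = False


#: Candidate gaps are searched with this slack factor on ``tol``; the
#: final fit-based acceptance is still at ``tol`` per member.
_SEARCH_SLACK = 2.0


def detect_ladders(ml: DeconMassList, steps=None, tol: float = 0.5,
                   mode: str | None = None) -> list[LadderHit]:
    """Find maximal glycoform ladders in a mass list.

    Adjacent ladder members must differ by a registered step; where
    several steps fit a gap, the smallest residual wins. Chains are grown
    greedily from entries that no other entry can precede, so reported
    ladders are not extendable on either side.

    Acceptance is fit-based: a chain is kept when every member lies within
    ``tol`` of its position on the least-squares-fitted ladder (base
    offset chosen to minimize the residuals). This is deliberately not a
    per-gap threshold — adjacent gaps carry the noise of two masses, so
    gap thresholding at ``tol`` throws away ladders whose members are all
    individually fine. Candidate gaps are searched with a small slack for
    the same reason; chains that fail the fit are split at their worst
    gaps and the consistent runs reported. Chains need at least two
    members; they are returned sorted by summed intensity (intensity
    plays no role in chain building itself).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if len(ml) < 2:
        return []
    if steps is None:
        steps = GLYCAN_STEPS.values()
    steps = [GLYCAN_STEPS[s] if isinstance(s, str) else s for s in steps]
    if mode is None:
        mode = ml.entries[0].mode
    search_tol = _SEARCH_SLACK * tol

    order = sorted(range(len(ml)), key=lambda i: ml.entries[i].mass)

    def best_step(gap: float):
        cand = [(abs(gap - s.delta(mode)), gap - s.delta(mode), s) for s in steps
                if abs(gap - s.delta(mode)) <= search_tol]
        return min(cand, key=lambda c: c[0]) if cand else None

    # successor candidates per entry (sorted-domain indices)
    succ: dict[int, list[tuple[float, float, int, str]]] = {i: [] for i in order}
    has_pred: set[int] = set()
    for a_pos, i in enumerate(order):
        mi = ml.entries[i].mass
        for j in order[a_pos + 1:]:
            gap = ml.entries[j].mass - mi
            if gap > max(s.delta(mode) for s in steps) + search_tol:
                break
            hit = best_step(gap)
            if hit is not None:
                succ[i].append((hit[0], hit[1], j, hit[2].name))
                has_pred.add(j)

    step_by_name = {s.name: s for s in steps}

    def fit_ok(members: list[int], names: list[str]) -> bool:
        cum = [0.0]
        for name in names:
            cum.append(cum[-1] + step_by_name[name].delta(mode))
        offs = [ml.entries[k].mass - c for k, c in zip(members, cum)]
        center = sum(offs) / len(offs)
        return all(abs(o - center) <= tol for o in offs)

    def emit(members, names, residuals, out):
        if len(members) < 2:
            return
        if fit_ok(members, names):
            out.append(LadderHit(
                base_mass=ml.entries[members[0]].mass,
                steps=list(names),
                members=list(members),
                residuals=list(residuals),
                summed_intensity=sum(ml.entries[k].intensity for k in members),
            ))
            return
        # split at the worst gap and retry the halves
        w = max(range(len(residuals)), key=lambda k: abs(residuals[k]))
        emit(members[: w + 1], names[:w], residuals[:w], out)
        emit(members[w + 1:], names[w + 1:], residuals[w + 1:], out)

    hits: list[LadderHit] = []
    for i in order:
        if i in has_pred or not succ[i]:
            continue
        members = [i]
        step_names: list[str] = []
        residuals: list[float] = []
        cur = i
        while succ[cur]:
            _aresid, resid, nxt, name = min(succ[cur], key=lambda c: c[0])
            members.append(nxt)
            step_names.append(name)
            residuals.append(resid)
            cur = nxt
        emit(members, step_names, residuals, hits)
    hits.sort(key=lambda h: -h.summed_intensity)
    return hits


def count_disulfides(m_nonreduced: float, m_reduced: float, tol: float = 0.1,
                     mode: str = "mono") -> DisulfideEstimate:
    """Count disulfide bridges from the reduced/nonreduced mass shift.

    n = round(delta / 2.01565); the estimate is accepted when the residual
    delta - n*step is within ``tol`` and the shift is not negative beyond
    tolerance.
    """
    if m_nonreduced <= 0 or m_reduced <= 0:
        raise ValueError("masses must be positive")
    step = DISULFIDE_STEP_MONO if mode == "mono" else DISULFIDE_STEP_AVG
    delta = m_reduced - m_nonreduced
    if delta < -tol:
        raise InconsistentMassesError(
            f"reduced mass below nonreduced by {-delta:.4f} Da (beyond tol {tol})"
        )
    n = max(0, round(delta / step))
    residual = delta - n * step
    return DisulfideEstimate(
        n_bridges=n,
        delta_mass=delta,
        residual=residual,
        accepted=abs(residual) <= tol,
    )


def relate_masses(ml: DeconMassList, deltas=None, tol: float = 0.5,
                  mode: str | None = None) -> list[ShiftRelation]:
    """Label all lighter->heavier pairs whose gap matches a named delta.

    ``deltas`` maps name -> (mono, avg) tuple or a single float used for
    both modes; defaults to the built-in registry (O, CO, H2O and the
    glycan units). The best-fitting (smallest-residual) delta names each
    pair; orientation is always from the lighter to the heavier mass.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if deltas is None:
        deltas = SHIFT_DELTAS
    if mode is None:
        mode = ml.entries[0].mode if len(ml) else "avg"
    k = 0 if mode == "mono" else 1

    def value(v):
        return v[k] if isinstance(v, (tuple, list)) else float(v)

    rels: list[ShiftRelation] = []
    for i, ei in enumerate(ml.entries):
        for j, ej in enumerate(ml.entries):
            if ej.mass <= ei.mass or i == j:
                continue
            gap = ej.mass - ei.mass
            cand = [(abs(gap - value(v)), name) for name, v in deltas.items()
                    if abs(gap - value(v)) <= tol]
            if cand:
                resid, name = min(cand)
                rels.append(ShiftRelation(i, j, ei.mass, ej.mass, name,
                                          gap - value(deltas[name])))
    return rels


def pair_conditions(nonred: DeconMassList, red: DeconMassList,
                    max_bridges: int = 20, tol: float = 0.1,
                    mode: str = "mono") -> list[ConditionPair]:
    """Pair nonreduced with reduced masses through n-disulfide shifts.

    Every cross-condition pair whose mass difference is n * 2.01565 Da for
    some 0 <= n <= max_bridges (within ``tol``) is reported; entries
    occurring in more than one pair are flagged ambiguous.
    """
    if max_bridges < 0:
        raise ValueError("max_bridges must be >= 0")
    pairs: list[ConditionPair] = []
    for i, en in enumerate(nonred.entries):
        for j, er in enumerate(red.entries):
            delta = er.mass - en.mass
            if delta < -tol:
                continue
            est = count_disulfides(en.mass, er.mass, tol=tol, mode=mode)
            if est.accepted and est.n_bridges <= max_bridges:
                pairs.append(ConditionPair(i, j, est))
    seen_n: dict[int, int] = {}
    seen_r: dict[int, int] = {}
    for p in pairs:
        seen_n[p.nonreduced_index] = seen_n.get(p.nonreduced_index, 0) + 1
        seen_r[p.reduced_index] = seen_r.get(p.reduced_index, 0) + 1
    for p in pairs:
        p.ambiguous = seen_n[p.nonreduced_index] > 1 or seen_r[p.reduced_index] > 1
    return pairs
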