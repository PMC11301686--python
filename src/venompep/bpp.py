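"""Modular consensus grammar for bradykinin-potentiating peptides (BPP).

Viperine BPP and their truncations follow a modular consensus

    pE X W (P Z){1,2} P (EI | KV) P P L E

with X mainly Lys/Asn/Arg (other residues occur but are rare), Z one of
Gly/Ser/Val, and extensive C-terminal truncation down to the tripeptide
core pEXW (the svMP-inhibitor tripeptides pEKW, pENW, pERW). This module
enumerates the grammar, parses peptides against it (classifying them into
the K/N/R-related families), and names substitutions of natriuretic
peptides against reference sequences such as lebetin 1β.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .masses import Peptide

__all__ = [
    "BppGrammar",
    "DEFAULT_GRAMMAR",
    "MotifParse",
    "NpReference",
    "LEBETIN_1B",
    "parse_bpp",
    "enumerate_bpp",
    "name_substitutions",
    "SubstitutionReport",
]


@dataclass(frozen=True)
class BppGrammar:
    """Alphabets and fixed blocks of the BPP consensus.

    ``x_alphabet`` is the canonical set for position 2; any other standard
    residue there still yields a parse but is flagged rare (family
    ``other``). The (P Z) unit repeats once or twice, followed by a
    mandatory P, a two-residue branch block, and the tail P P L E.
    """

    x_alphabet: frozenset[str] = frozenset({"K", "N", "R"})
    z_alphabet: frozenset[str] = frozenset({"G", "S", "V"})
    repeats: frozenset[int] = frozenset({1, 2})
    branches: frozenset[str] = frozenset({"EI", "KV"})
    tail: str = "PPLE"

    def full_templates(self, x_codes: tuple[str, ...] | None = None
                       ) -> list[tuple[str, ...]]:
        """All full-length residue tuples (``pE`` counts as one residue)."""
        xs = x_codes if x_codes is not None else sorted(self.x_alphabet)
        out: list[tuple[str, ...]] = []
        for x in xs:
            for r in sorted(self.repeats):
                for zs in product(sorted(self.z_alphabet), repeat=r):
                    for br in sorted(self.branches):
                        body: list[str] = ["pE", x, "W"]
                        for z in zs:
                            body += ["P", z]
                        body += ["P", br[0], br[1]]
                        body += list(self.tail)
                        out.append(tuple(body))
        return out


DEFAULT_GRAMMAR = BppGrammar()

#: The short natriuretic peptide lebetin 1β, the reference viperid NP.
@dataclass(frozen=True)
class NpReference:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isupper():
            raise ValueError("reference sequence must be non-empty uppercase codes")


LEBETIN_1B = NpReference("lebetin 1beta", "DNKPPKKGPPNG")


@dataclass
class MotifParse:
    """Result of matching a peptide against the BPP grammar.

    ``truncation`` is the number of residues missing from the C-terminus of
    the best-matching full-length template (None when only the pEXW core
    matched in lenient mode). ``deviations`` lists tolerated
    ``(position, template_residue, observed_residue)`` mismatches.
    ``family`` is the position-2 classification: K, N, R or ``other``.
    """

    matched: bool
    family: str | None = None
    repeat: int | None = None
    z_residues: tuple[str, ...] = ()
    branch: str | None = None
    truncation: int | None = None
    deviations: list[tuple[int, str, str]] = field(default_factory=list)
    rare_x: bool = False
    core_only: bool = False
    stripped_mods: bool = False
    template: tuple[str, ...] | None = None


def _template_parts(tpl: tuple[str, ...], grammar: BppGrammar
                    ) -> tuple[int, tuple[str, ...], str]:
    """Recover (repeat, z residues, branch) from a full template tuple."""
    n_rep = (len(tpl) - 10) // 2  # 10 fixed residues outside the (P Z) units
    zs = tuple(tpl[4 + 2 * i] for i in range(n_rep))
    branch = tpl[3 + 2 * n_rep + 1] + tpl[3 + 2 * n_rep + 2]
    return n_rep, zs, branch


def parse_bpp(seq: "Peptide | str", strict: bool = False,
              grammar: BppGrammar = DEFAULT_GRAMMAR,
              max_deviations: int = 1) -> MotifParse:
    """Longest-prefix match of a peptide against the BPP grammar.

    Modifications (e.g. Trp oxidation) are stripped before matching and
    recorded via ``stripped_mods``. Strict mode requires the sequence to be
    an exact prefix of a full-length grammar sequence. Lenient mode
    tolerates up to ``max_deviations`` substitutions outside the pE/W
    anchors; if even that fails but the pEXW core is intact, the parse
    still reports ``matched=True`` with ``core_only=True`` and every
    mismatch against the closest template listed as a deviation.
    """
    p = seq if isinstance(seq, Peptide) else Peptide.parse(seq)
    stripped = bool(p.mods)
    res = p.residues
    out = MotifParse(matched=False, stripped_mods=stripped)
    if len(res) < 3 or res[0] != "pE" or res[2] != "W":
        return out
    x = res[1]
    rare = x not in grammar.x_alphabet
    family = x if not rare else "other"

    budget = 0 if strict else max_deviations
    best: tuple[int, int, tuple[str, ...], list] | None = None  # (dev, trunc, tpl, devs)
    closest: tuple[int, tuple[str, ...], list] | None = None
    for tpl in grammar.full_templates(x_codes=(x,)):
        if len(res) > len(tpl):
            continue
        devs = [
            (i + 1, tpl[i], res[i])
            for i in range(len(res))
            if res[i] != tpl[i]
        ]
        # anchors pE (1) and W (3) already enforced; X defines the template
        trunc = len(tpl) - len(res)
        key = (len(devs), trunc)
        if closest is None or key < (len(closest[2]), len(closest[1]) - len(res)):
            closest = (trunc, tpl, devs)
        if len(devs) <= budget:
            if best is None or key < (len(best[3]), best[1]):
                best = (len(devs), trunc, tpl, devs)

    if best is not None:
        _n, trunc, tpl, devs = best
        n_rep, zs, branch = _template_parts(tpl, grammar)
        matched_len = len(res)
        out.matched = True
        out.family = family
        out.rare_x = rare
        out.truncation = trunc
        out.deviations = devs
        out.template = tpl
        # only report the blocks the sequence actually reaches
        out.repeat = n_rep if matched_len >= 4 + 2 * n_rep else None
        out.z_residues = tuple(z for i, z in enumerate(zs) if matched_len >= 5 + 2 * i)
        out.branch = branch if matched_len >= 2 * n_rep + 6 else None
        return out

    if not strict:
        # pEXW core is intact: accept, flag everything after it as deviation
        out.matched = True
        out.family = family
        out.rare_x = rare
        out.core_only = True
        if closest is not None:
            out.template = closest[1]
            out.deviations = closest[2]
        return out
    return out


def enumerate_bpp(x: set[str] | None = None, z: set[str] | None = None,
                  repeats: set[int] | None = None,
                  branches: set[str] | None = None,
                  min_len: int = 3, full_only: bool = False) -> list[str]:
    """Enumerate grammar sequences (full length and C-terminal truncations).

    Lengths count ``pE`` as one residue; ``min_len`` below 3 (the pEXW
    core) is rejected. Output is deduplicated and lexicographically sorted.
    """
    if min_len < 3:
        raise ValueError("min_len below the pEXW core (3) is not meaningful")
    g = BppGrammar(
        x_alphabet=frozenset(x) if x else DEFAULT_GRAMMAR.x_alphabet,
        z_alphabet=frozenset(z) if z else DEFAULT_GRAMMAR.z_alphabet,
        repeats=frozenset(repeats) if repeats else DEFAULT_GRAMMAR.repeats,
        branches=frozenset(branches) if branches else DEFAULT_GRAMMAR.branches,
    )
    seqs: set[str] = set()
    for tpl in g.full_templates():
        if full_only:
            seqs.add("".join(tpl))
            continue
        for cut in range(min_len, len(tpl) + 1):
            seqs.add("".join(tpl[:cut]))
    return sorted(seqs)


@dataclass(frozen=True)
class Substitution:
    ref_pos: int  # 1-based on the reference
    ref_res: str
    query_res: str

    @property
    def label(self) -> str:
        """1-based label, e.g. K3E for Lys at reference position 3 -> Glu."""
        return f"{self.ref_res}{self.ref_pos}{self.query_res}"

    @property
    def label_legacy(self) -> str:
        """0-based label as sometimes used in the venom NP literature
        (numbering conventions there are not fully consistent)."""
        return f"{self.ref_res}{self.ref_pos - 1}{self.query_res}"


@dataclass
class SubstitutionReport:
    """Ungapped comparison of a query peptide against an NP reference."""

    reference: NpReference
    offset: int
    substitutions: list[Substitution] = field(default_factory=list)
    n_term_extension: str = ""
    c_term_extension: str = ""
    n_term_truncation: str = ""
    c_term_truncation: str = ""

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.substitutions]


def name_substitutions(query: str, ref: NpReference = LEBETIN_1B,
                       offset: int = 0) -> SubstitutionReport:
    """Name substitutions of ``query`` against a reference (ungapped).

    Query position ``i`` (1-based) aligns to reference position
    ``i + offset``; negative offsets therefore describe N-terminal
    extensions of the query. Terminal extensions and truncations are
    reported separately from substitutions.
    """
    q = query.strip().upper()
    r = ref.sequence
    # overlap in reference coordinates (1-based)
    lo = max(1, 1 + offset)
    hi = min(len(r), len(q) + offset)
    if hi < lo:
        raise ValueError("offset leaves no overlap between query and reference")
    rep = SubstitutionReport(reference=ref, offset=offset)
    for rpos in range(lo, hi + 1):
        qres = q[rpos - offset - 1]
        rres = r[rpos - 1]
        if qres != rres:
            rep.substitutions.append(Substitution(rpos, rres, qres))
    rep.n_term_extension = q[: lo - 1 - offset]
    rep.c_term_extension = q[hi - offset:]
    rep.n_term_truncation = r[: lo - 1]
    rep.c_term_truncation = r[hi:]
    return rep
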