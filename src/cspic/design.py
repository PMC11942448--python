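"""Pedigree bookkeeping and prediction-type taxonomies.

A connected set of biparental DH populations and their test-cross hybrid
populations defines, for every ordered (training, test) population pair, a
prediction type:

* DH pairs — ``full-sib`` (same population), ``half-sib`` (one shared
  founder parent, annotated with whether the two non-shared parents belong
  to the same heterotic group), or ``non-sib`` (no shared parent).
* Hybrid pairs — a seven-way cascade: ``In_Group`` (same hybrid
  population), ``Same_DH`` (same source DH population, different tester),
  ``Same_Tester`` (same tester, different DH population), ``Tri_Group``
  (the heterotic groups of {parent1, parent2, tester} coincide as sets),
  then ``M2``/``M1``/``M0`` by the number of shared inbred lines among
  {parent1, parent2, tester}.

The cascade order runs from most to least specific; a pair matching an
earlier rule never falls through to a later one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

DH_CATEGORIES = ("full-sib", "half-sib", "non-sib")
HYBRID_CATEGORIES = (
    "In_Group",
    "Same_DH",
    "Same_Tester",
    "Tri_Group",
    "M2",
    "M1",
    "M0",
)
SAMEDH_SUBTYPES = ("same_DH", "rand_DH", "diff_DH")


@dataclass(frozen=True)
class LineInfo:
    """One line in the pedigree: founder, tester, DH line, or hybrid."""

    id: str
    group: str | None
    role: str  # founder | tester | DH | hybrid
    parent1: str | None = None
    parent2: str | None = None


@dataclass(frozen=True)
class DHPopulationSpec:
    pop_id: str
    parent1: str
    parent2: str
    n_lines: int = 100


@dataclass(frozen=True)
class HybridPopulationSpec:
    pop_id: str
    dh_pop: str
    tester: str


@dataclass
class PopulationDesign:
    """Group map plus DH- and hybrid-population composition."""

    groups: dict[str, str]
    dh_pops: dict[str, DHPopulationSpec] = field(default_factory=dict)
    hybrid_pops: dict[str, HybridPopulationSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for spec in self.dh_pops.values():
            for p in (spec.parent1, spec.parent2):
                if p not in self.groups:
                    raise ValueError(f"parent {p} has no heterotic-group label")
        for spec in self.hybrid_pops.values():
            if spec.dh_pop not in self.dh_pops:
                raise ValueError(f"unknown DH population {spec.dh_pop}")
            if spec.tester not in self.groups:
                raise ValueError(f"tester {spec.tester} has no group label")

    # ------------------------------------------------------------------ #

    def dh_parents(self, pop_id: str) -> tuple[str, str]:
        spec = self._dh(pop_id)
        return spec.parent1, spec.parent2

    def hybrid_components(self, hpop_id: str) -> tuple[str, str, str]:
        """(parent1, parent2, tester) of a hybrid population."""
        spec = self._hybrid(hpop_id)
        p1, p2 = self.dh_parents(spec.dh_pop)
        return p1, p2, spec.tester

    def _dh(self, pop_id: str) -> DHPopulationSpec:
        try:
            return self.dh_pops[pop_id]
        except KeyError:
            raise KeyError(f"unknown DH population id: {pop_id}") from None

    def _hybrid(self, hpop_id: str) -> HybridPopulationSpec:
        try:
            return self.hybrid_pops[hpop_id]
        except KeyError:
            raise KeyError(f"unknown hybrid population id: {hpop_id}") from None

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "dh_pops": [
                {
                    "pop_id": s.pop_id,
                    "parent1": s.parent1,
                    "parent2": s.parent2,
                    "n_lines": s.n_lines,
                }
                for s in self.dh_pops.values()
            ],
            "hybrid_pops": [
                {"pop_id": s.pop_id, "dh_pop": s.dh_pop, "tester": s.tester}
                for s in self.hybrid_pops.values()
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationDesign":
        return cls(
            groups=dict(d["groups"]),
            dh_pops={
                s["pop_id"]: DHPopulationSpec(
                    s["pop_id"], s["parent1"], s["parent2"], s.get("n_lines", 100)
                )
                for s in d["dh_pops"]
            },
            hybrid_pops={
                s["pop_id"]: HybridPopulationSpec(
                    s["pop_id"], s["dh_pop"], s["tester"]
                )
                for s in d["hybrid_pops"]
            },
        )

    @classmethod
    def from_json(cls, path) -> "PopulationDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------- #
# default design: five founders in four heterotic groups, five DH
# populations, seven testers, fifteen test-cross populations on the
# triangular heterotic pattern (each tester drawn from a third group
# distinct from both DH founders' groups).

DEFAULT_GROUPS = {
    "C783": "X",
    "C229": "Reid",
    "C116A": "SPT",
    "UH306": "Early",
    "EH": "Early",
    "J2416": "SPT",
    "C2404": "Reid",
    "Z58": "Reid",
}

DEFAULT_DH_POPS = [
    ("POP1", "C783", "C229", 124),
    ("POP2", "C783", "UH306", 97),
    ("POP3", "C783", "EH", 134),
    ("POP4", "C229", "UH306", 91),
    ("POP5", "C783", "C116A", 89),
]

# Three testers per DH population. The pairings named in published
# descriptions of this design (POP1-4 x C116A; POP1, POP4 x J2416; POP5 x
# {C229, C2404, Z58}; POP2/Z58; POP3/Z58; POP1/EH) are wired verbatim; the
# remaining three slots are filled here on the triangular rule and are
# editable through the design JSON.
DEFAULT_HYBRID_POPS = [
    ("POP1", "C116A"),
    ("POP1", "J2416"),
    ("POP1", "EH"),
    ("POP2", "C116A"),
    ("POP2", "Z58"),
    ("POP2", "C2404"),
    ("POP3", "C116A"),
    ("POP3", "Z58"),
    ("POP3", "J2416"),
    ("POP4", "C116A"),
    ("POP4", "J2416"),
    ("POP4", "C783"),
    ("POP5", "C229"),
    ("POP5", "C2404"),
    ("POP5", "Z58"),
]


def default_design() -> PopulationDesign:
    dh = {
        pid: DHPopulationSpec(pid, p1, p2, n)
        for pid, p1, p2, n in DEFAULT_DH_POPS
    }
    hy = {
        f"{pop}/{tester}": HybridPopulationSpec(f"{pop}/{tester}", pop, tester)
        for pop, tester in DEFAULT_HYBRID_POPS
    }
    return PopulationDesign(groups=dict(DEFAULT_GROUPS), dh_pops=dh, hybrid_pops=hy)


# ---------------------------------------------------------------------- #
# classification


@dataclass(frozen=True)
class DHPairLabel:
    category: str  # full-sib | half-sib | non-sib
    shared_parent: str | None = None
    nonshared_same_group: bool | None = None


def classify_dh_pair(
    pop_a: str, pop_b: str, design: PopulationDesign
) -> DHPairLabel:
    """Sib relationship of two DH populations from their founder parents."""
    pa = set(design.dh_parents(pop_a))
    pb = set(design.dh_parents(pop_b))
    if pop_a == pop_b:
        return DHPairLabel("full-sib")
    shared = pa & pb
    if len(shared) == 1:
        (sp,) = shared
        non_a = (pa - shared).pop()
        non_b = (pb - shared).pop()
        same = design.groups[non_a] == design.groups[non_b]
        return DHPairLabel("half-sib", shared_parent=sp, nonshared_same_group=same)
    if len(shared) == 0:
        return DHPairLabel("non-sib")
    # two shared parents but distinct pop ids: same cross replicated
    return DHPairLabel("full-sib")


def classify_hybrid_pair(
    hpop_a: str, hpop_b: str, design: PopulationDesign
) -> str:
    """Seven-way prediction-type cascade for two hybrid populations."""
    sa = design._hybrid(hpop_a)
    sb = design._hybrid(hpop_b)
    if hpop_a == hpop_b:
        return "In_Group"
    if sa.dh_pop == sb.dh_pop and sa.tester != sb.tester:
        return "Same_DH"
    if sa.tester == sb.tester and sa.dh_pop != sb.dh_pop:
        return "Same_Tester"
    comp_a = design.hybrid_components(hpop_a)
    comp_b = design.hybrid_components(hpop_b)
    groups_a = {design.groups[x] for x in comp_a}
    groups_b = {design.groups[x] for x in comp_b}
    if groups_a == groups_b:
        return "Tri_Group"
    n_shared = len(set(comp_a) & set(comp_b))
    if n_shared >= 2:
        return "M2"
    return f"M{n_shared}"


def hybrid_label_matrix(design: PopulationDesign) -> pd.DataFrame:
    """Full ordered train x test label matrix over all hybrid populations."""
    pops = list(design.hybrid_pops)
    data = {
        b: [classify_hybrid_pair(a, b, design) for a in pops] for b in pops
    }
    return pd.DataFrame(data, index=pops)


def dh_label_matrix(design: PopulationDesign) -> pd.DataFrame:
    pops = list(design.dh_pops)
    data = {
        b: [classify_dh_pair(a, b, design).category for a in pops]
        for b in pops
    }
    return pd.DataFrame(data, index=pops)


# ---------------------------------------------------------------------- #
# Same_DH sub-typing


def dh_line_of(hybrid_id: str) -> str:
    """DH-line component of a hybrid id of the form '<dh_id>/<tester_id>'."""
    if "/" not in hybrid_id:
        raise ValueError(f"not a hybrid id: {hybrid_id}")
    return hybrid_id.rsplit("/", 1)[0]


def samedh_subtype(train_ids, test_ids) -> str:
    """Classify a sampled Same_DH task by DH-line overlap.

    ``same_DH`` — every test hybrid's DH line also appears among the
    training hybrids' DH lines; ``diff_DH`` — the two DH-line sets are
    disjoint; anything else is ``rand_DH``.
    """
    train_dh = {dh_line_of(i) for i in train_ids}
    test_dh = {dh_line_of(i) for i in test_ids}
    if test_dh <= train_dh:
        return "same_DH"
    if not (test_dh & train_dh):
        return "diff_DH"
    return "rand_DH"


@dataclass
class PredictionTask:
    """A sampled (training, test) assignment with its taxonomy label."""

    train_pop: str
    test_pop: str
    train_ids: list[str]
    test_ids: list[str]
    category: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.train_pop == self.test_pop:
            if set(self.train_ids) & set(self.test_ids):
                raise ValueError(
                    "training and test samples overlap within one population"
                )
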