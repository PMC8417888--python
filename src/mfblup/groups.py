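"""Breed-composition propagation, group assignment, heterosis covariates.

The composite population is described by the NABC system: four biological
types N (zebu), A (adapted taurine), B (British taurine) and C (Continental
taurine).  Every animal carries a 4-vector of breed fractions.  Missing
parents are assigned to unknown-parent groups / metafounders from the breed
composition inferred for the missing parent, under one of two definitions:

* GG4  — one group per biological type;
* GG10 — purebred groups plus two-, three- and four-way cross groups, with
  the sparse crosses merged ({NA, AB, AC, BC} and {NAB, NAC, ABC}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError, UNKNOWN

BREEDS = ("N", "A", "B", "C")

#: the six direct-heterozygosity breed pairs, column order of the covariates
HET_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
HET_COLUMNS = tuple(f"het_{BREEDS[a]}{BREEDS[b]}" for a, b in HET_PAIRS)

GG4_LABELS = ["N", "A", "B", "C"]
GG10_LABELS = ["N", "A", "B", "C", "NA+AB+AC+BC", "NB", "NC",
               "NAB+NAC+ABC", "NBC", "NABC"]

# pattern (frozenset of breed indices) -> GG10 label
_GG10_PATTERNS = {
    frozenset({0}): "N", frozenset({1}): "A",
    frozenset({2}): "B", frozenset({3}): "C",
    frozenset({0, 1}): "NA+AB+AC+BC", frozenset({1, 2}): "NA+AB+AC+BC",
    frozenset({1, 3}): "NA+AB+AC+BC", frozenset({2, 3}): "NA+AB+AC+BC",
    frozenset({0, 2}): "NB", frozenset({0, 3}): "NC",
    frozenset({0, 1, 2}): "NAB+NAC+ABC", frozenset({0, 1, 3}): "NAB+NAC+ABC",
    frozenset({1, 2, 3}): "NAB+NAC+ABC",
    frozenset({0, 2, 3}): "NBC",
    frozenset({0, 1, 2, 3}): "NABC",
}


@dataclass
class GroupDefinition:
    """GG4 or GG10 group definition.

    ``epsilon`` is the minimum breed fraction for a breed to count in a
    GG10 combination pattern (default 1/16, half the smallest fraction used
    in composite formation).
    """

    mode: str = "GG4"
    epsilon: float = 1.0 / 16.0
    labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in ("GG4", "GG10"):
            raise ValueError("mode must be 'GG4' or 'GG10'")
        self.labels = list(GG4_LABELS if self.mode == "GG4" else GG10_LABELS)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def fraction_vectors(self) -> np.ndarray:
        """Representative breed-fraction vector per group (rows sum to 1).

        Merged GG10 groups use the equally weighted mean of their member
        patterns' uniform fraction vectors.
        """
        members = {lab: [] for lab in self.labels}
        if self.mode == "GG4":
            for j, lab in enumerate(self.labels):
                v = np.zeros(4)
                v[j] = 1.0
                members[lab].append(v)
        else:
            for pat, lab in _GG10_PATTERNS.items():
                v = np.zeros(4)
                v[list(pat)] = 1.0 / len(pat)
                members[lab].append(v)
        return np.array([np.mean(members[lab], axis=0) for lab in self.labels])


@dataclass
class GroupAssignment:
    """Group code for every unknown-parent slot (-1 where the parent is known)."""

    definition: GroupDefinition
    sire_group: np.ndarray
    dam_group: np.ndarray

    def used_groups(self) -> np.ndarray:
        both = np.concatenate([self.sire_group, self.dam_group])
        return np.unique(both[both >= 0])


@dataclass
class CompositionResult:
    """Propagated compositions and inferred missing-parent compositions."""

    comp: np.ndarray          # (n, 4) animal compositions (NaN if undetermined)
    sire_comp: np.ndarray     # (n, 4) composition of each animal's sire slot
    dam_comp: np.ndarray
    no_information: np.ndarray  # animals whose composition never resolved


def _clip_renorm(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, None)
    s = v.sum()
    if s <= 0:
        return np.full(4, np.nan)
    return v / s


def propagate_breed_composition(ped: Pedigree,
                                max_iter: int | None = None) -> CompositionResult:
    """Complete breed compositions and infer missing-parent compositions.

    Iterates to a fixed point:

    * an animal without composition takes the mean of its parents' (known
      or inferred) compositions;
    * both parents unknown -> each missing parent takes the animal's own
      composition;
    * one parent known -> the missing parent takes
      ``clip-and-renormalize(2 c_animal - c_known_parent)`` (mid-parent
      algebra).
    """
    n = ped.n
    comp = (np.full((n, 4), np.nan) if ped.breed_comp is None
            else ped.breed_comp.copy())
    sire_comp = np.full((n, 4), np.nan)
    dam_comp = np.full((n, 4), np.nan)
    if max_iter is None:
        max_iter = n + 1
    for _ in range(max_iter):
        changed = False
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            cs = comp[s] if s != UNKNOWN else sire_comp[i]
            cd = comp[d] if d != UNKNOWN else dam_comp[i]
            if np.isnan(comp[i]).any():
                if not (np.isnan(cs).any() or np.isnan(cd).any()):
                    comp[i] = 0.5 * (cs + cd)
                    changed = True
            if np.isnan(comp[i]).any():
                continue
            if s == UNKNOWN and np.isnan(sire_comp[i]).any():
                sire_comp[i] = (comp[i] if d == UNKNOWN or np.isnan(cd).any()
                                else _clip_renorm(2.0 * comp[i] - cd))
                changed = True
            if d == UNKNOWN and np.isnan(dam_comp[i]).any():
                dam_comp[i] = (comp[i] if s == UNKNOWN or np.isnan(cs).any()
                               else _clip_renorm(2.0 * comp[i] - cs))
                changed = True
        if not changed:
            break
    no_info = np.isnan(comp).any(axis=1)
    return CompositionResult(comp, sire_comp, dam_comp, no_info)


def _pattern(frac: np.ndarray, eps: float) -> frozenset[int]:
    return frozenset(np.flatnonzero(frac >= eps).tolist())


def assign_groups(ped: Pedigree, comps: CompositionResult,
                  definition: GroupDefinition) -> GroupAssignment:
    """Assign every unknown-parent slot to a group.

    GG4: argmax of the inferred parent composition (ties break by the fixed
    priority N > A > B > C).  GG10: the set of breeds with fraction >=
    epsilon maps to the ten merged labels; for a two-breed animal with both
    parents unknown, one parent is assigned to each breed (the NA -> N and
    A rule).
    """
    n = ped.n
    label_idx = {lab: j for j, lab in enumerate(definition.labels)}
    sg = np.full(n, -1, dtype=np.int64)
    dg = np.full(n, -1, dtype=np.int64)
    eps = definition.epsilon
    for i in range(n):
        s_unk = ped.sire[i] == UNKNOWN
        d_unk = ped.dam[i] == UNKNOWN
        if not (s_unk or d_unk):
            continue
        if comps.no_information[i]:
            raise PedigreeError(
                f"animal {i} has a missing parent but no breed information")
        both = s_unk and d_unk
        if definition.mode == "GG10" and both:
            pat = sorted(_pattern(comps.comp[i], eps))
            if len(pat) == 2:
                # one parent per breed, sire takes the priority breed
                sg[i] = label_idx[GG10_LABELS[pat[0]]]
                dg[i] = label_idx[GG10_LABELS[pat[1]]]
                continue
        for unk, slot_comp, out in ((s_unk, comps.sire_comp[i], sg),
                                    (d_unk, comps.dam_comp[i], dg)):
            if not unk:
                continue
            frac = slot_comp
            if np.isnan(frac).any():
                frac = comps.comp[i]
            if definition.mode == "GG4":
                out[i] = int(np.argmax(frac))  # argmax keeps N>A>B>C priority
            else:
                pat = _pattern(frac, eps)
                if not pat:
                    raise PedigreeError(f"empty breed pattern for animal {i}")
                out[i] = label_idx[_GG10_PATTERNS[pat]]
    return GroupAssignment(definition, sg, dg)


def _pair_heterozygosity(cs: np.ndarray, cd: np.ndarray) -> np.ndarray:
    """Six pairwise expected-heterozygosity covariates for one mating."""
    out = np.empty(len(HET_PAIRS))
    for j, (a, b) in enumerate(HET_PAIRS):
        out[j] = cs[a] * cd[b] + cs[b] * cd[a]
    return out


def heterosis_covariates(ped: Pedigree,
                         comps: CompositionResult | None = None) -> pd.DataFrame:
    """Per-animal heterosis covariates.

    Direct heterozygosity for breed pair (b, b') is
    ``s_b d_b' + s_b' d_b`` from the sire (s) and dam (d) compositions —
    six pairwise covariates.  Total maternal heterozygosity is the dam's own
    summed pairwise heterozygosity, computed from her parents; 0 and flagged
    when the dam (or her parents' compositions) are unavailable.
    """
    if comps is None:
        comps = propagate_breed_composition(ped)
    n = ped.n

    def parent_comp(i: int, which: str) -> np.ndarray:
        par = ped.sire[i] if which == "s" else ped.dam[i]
        if par != UNKNOWN:
            return comps.comp[par]
        return comps.sire_comp[i] if which == "s" else comps.dam_comp[i]

    direct = np.zeros((n, len(HET_PAIRS)))
    maternal = np.zeros(n)
    no_direct = np.zeros(n, dtype=bool)   # own heterozygosity unavailable
    flagged = np.zeros(n, dtype=bool)     # maternal heterozygosity missing
    own_het = np.zeros(n)  # each animal's own summed heterozygosity
    for i in range(n):
        cs, cd = parent_comp(i, "s"), parent_comp(i, "d")
        if np.isnan(cs).any() or np.isnan(cd).any():
            no_direct[i] = True
            continue
        direct[i] = _pair_heterozygosity(cs, cd)
        own_het[i] = direct[i].sum()
    for i in range(n):
        d = ped.dam[i]
        if d == UNKNOWN or no_direct[d]:
            flagged[i] = True
        else:
            maternal[i] = own_het[d]
    out = pd.DataFrame(direct, columns=list(HET_COLUMNS))
    out["het_maternal"] = maternal
    out["het_flagged"] = flagged
    return out
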