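"""Branch-specific TE origination on a dated phylogeny.

Families are scored present (1), absent (0), or possibly present (0.5)
per species from the bp attributable to the family in that genome
(thresholds 5,000 and 500 bp).  A family is assigned to the stem branch
of the smallest clade containing all its score-1 species when the
clade's presence sum reaches a clade-size-dependent threshold (n - 0.5
by default) and every tip outside the clade scores 0.  Rates are
assigned-family counts divided by branch durations in Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repeat_io import DatedTree, RepeatHit, _branch_id

__all__ = [
    "PresenceMatrix",
    "BranchAssignment",
    "score_presence",
    "subclade_threshold",
    "presence_matrix",
    "assign_branch",
    "origination_rates",
    "lineage_contribution",
]

PRESENT_BP = 5000
ABSENT_BP = 500


def score_presence(bp: int, present_bp: int = PRESENT_BP,
                   absent_bp: int = ABSENT_BP) -> float:
    """Presence score from bp attributable to a family in one genome.

    1 when bp >= 5,000; 0 when bp < 500; 0.5 in between.
    """
    if bp < 0:
        raise ValueError(f"negative bp count {bp}")
    if bp >= present_bp:
        return 1.0
    if bp < absent_bp:
        return 0.0
    return 0.5


def subclade_threshold(n_members: int,
                       overrides: Mapping[int, float] | None = None) -> float:
    """Presence-sum threshold for calling a family specific to a clade.

    Default rule: n_members - 0.5 (a 4-member clade needs a presence sum
    of 3.5).  Per-size overrides are accepted because thresholds were
    historically set per subclade.
    """
    if n_members < 2:
        raise ValueError("subclade threshold defined for clades of >= 2 members")
    if overrides and n_members in overrides:
        return float(overrides[n_members])
    return n_members - 0.5


@dataclass
class PresenceMatrix:
    """Family x species presence scores, with the raw bp counts retained."""

    scores: pd.DataFrame   # families x species, values in {0, 0.5, 1}
    bp: pd.DataFrame       # families x species, integer bp

    @property
    def families(self) -> list[str]:
        return list(self.scores.index)

    @property
    def species(self) -> list[str]:
        return list(self.scores.columns)


def presence_matrix(hits_by_species: Mapping[str, Sequence[RepeatHit]],
                    families: Iterable[str] | None = None) -> PresenceMatrix:
    """Score every family in every species from summed annotated bp.

    Uses the full annotation (no age-stratum filter): presence reflects
    everything attributable to the family in the assembly.
    """
    species = sorted(hits_by_species)
    bp: dict[tuple[str, str], int] = {}
    fam_set: set[str] = set(families) if families is not None else set()
    for sp, hits in hits_by_species.items():
        for h in hits:
            if families is not None and h.family_name not in fam_set:
                continue
            fam_set.add(h.family_name)
            bp[(h.family_name, sp)] = bp.get((h.family_name, sp), 0) + h.length_bp
    fams = sorted(fam_set)
    bp_df = pd.DataFrame(0, index=pd.Index(fams, name="family_name"),
                         columns=species, dtype=int)
    for (fam, sp), n in bp.items():
        bp_df.loc[fam, sp] = n
    scores = bp_df.map(score_presence)
    return PresenceMatrix(scores=scores, bp=bp_df)


@dataclass
class BranchAssignment:
    """Family -> originating branch, with reasons for the unassigned."""

    assigned: dict      # family -> branch_id
    unassigned: dict    # family -> reason
    tree: DatedTree = field(repr=False)

    def counts_by_branch(self) -> dict:
        counts: dict[str, int] = {b.branch_id: 0 for b in self.tree.branches()}
        for branch_id in self.assigned.values():
            counts[branch_id] += 1
        return counts


def assign_branch(presence: PresenceMatrix, tree: DatedTree,
                  threshold_overrides: Mapping[int, float] | None = None,
                  allow_possible_outside: bool = False) -> BranchAssignment:
    """Assign each family to the stem branch of its origin clade.

    For each family, S is the set of species scoring 1.  The candidate
    clade C is the smallest clade of the tree containing S.  The family
    is assigned to C's stem branch iff (i) the presence sum over C's
    tips reaches subclade_threshold(|C|) (a single-tip clade requires a
    score of 1) and (ii) every tip outside C scores 0 (or, when
    ``allow_possible_outside`` is set, scores < 1).  Otherwise the family
    is recorded unassigned with a reason; nothing is silently dropped.
    """
    tips = set(tree.tip_labels)
    if set(presence.species) != tips:
        raise ValueError(
            f"presence columns {sorted(presence.species)} != tree tips {sorted(tips)}"
        )
    assigned: dict[str, str] = {}
    unassigned: dict[str, str] = {}
    for fam in presence.families:
        row = presence.scores.loc[fam]
        S = frozenset(sp for sp in presence.species if row[sp] == 1.0)
        if not S:
            unassigned[fam] = "no-species-scored-present"
            continue
        C = tree.mrca_tips(S)
        if len(C) == len(tips):
            unassigned[fam] = "origin-predates-root"
            continue
        in_sum = float(sum(row[sp] for sp in C))
        if len(C) == 1:
            ok_sum = in_sum == 1.0
            threshold = 1.0
        else:
            threshold = subclade_threshold(len(C), threshold_overrides)
            ok_sum = in_sum >= threshold
        if not ok_sum:
            unassigned[fam] = (
                f"presence-sum-below-threshold ({in_sum} < {threshold})"
            )
            continue
        outside_limit = 0.5 if allow_possible_outside else 0.0
        bad_outside = [sp for sp in tips - C if row[sp] > outside_limit]
        if bad_outside:
            unassigned[fam] = "outside-clade-nonzero"
            continue
        assigned[fam] = _branch_id(C)
    return BranchAssignment(assigned=assigned, unassigned=unassigned, tree=tree)


def origination_rates(assignment: BranchAssignment, tree: DatedTree,
                      family_classes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-branch origination rates: assigned families / branch duration.

    Returns one row per branch with duration, counts (per class when
    ``family_classes`` maps family -> class label) and rates in
    families/Myr.
    """
    counts = assignment.counts_by_branch()
    rows = []
    classes = sorted(set(family_classes.values())) if family_classes else []
    by_class: dict[tuple[str, str], int] = {}
    if family_classes:
        for fam, branch_id in assignment.assigned.items():
            cls = family_classes.get(fam, "Unknown")
            by_class[(branch_id, cls)] = by_class.get((branch_id, cls), 0) + 1
    for b in tree.branches():
        n = counts[b.branch_id]
        if b.duration_myr <= 0:
            if n > 0:
                raise ValueError(
                    f"branch {b.branch_id} has zero duration but {n} families"
                )
            rate = 0.0
        else:
            rate = n / b.duration_myr
        row = {
            "branch_id": b.branch_id,
            "is_terminal": b.is_terminal,
            "duration_myr": b.duration_myr,
            "n_families": n,
            "rate_per_myr": rate,
        }
        for cls in classes:
            row[f"n_{cls}"] = by_class.get((b.branch_id, cls), 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("branch_id")


def lineage_contribution(assignment: BranchAssignment,
                         hits_by_species: Mapping[str, Sequence[RepeatHit]],
                         genomes: Mapping[str, int],
                         branch_id: str,
                         clade_tips: Iterable[str] | None = None) -> pd.DataFrame:
    """DNA deposited by the families that originated on one branch.

    Per species in the clade below the branch: summed bp of all hits of
    branch-assigned families, and the proportion of the genome that bp
    represents.  A summary row holds the clade means.
    """
    branch = assignment.tree.branch(branch_id)
    tips = set(clade_tips) if clade_tips is not None else set(branch.tips)
    if not tips <= set(branch.tips):
        raise ValueError("clade tips must descend from the branch")
    fams = {f for f, b in assignment.assigned.items() if b == branch_id}
    rows = []
    for sp in sorted(tips):
        if sp not in genomes:
            raise ValueError(f"no genome size for species {sp}")
        bp = sum(h.length_bp for h in hits_by_species.get(sp, ())
                 if h.family_name in fams)
        rows.append({"species_id": sp, "bp": bp,
                     "proportion": bp / genomes[sp]})
    df = pd.DataFrame(rows).set_index("species_id")
    df.attrs["branch_id"] = branch_id
    df.attrs["n_families"] = len(fams)
    df.attrs["clade_mean_bp"] = float(df["bp"].mean()) if len(df) else float("nan")
    df.attrs["clade_mean_proportion"] = (
        float(df["proportion"].mean()) if len(df) else float("nan")
    )
    return df
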