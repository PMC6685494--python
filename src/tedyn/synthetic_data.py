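"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators emulate the study's data shapes.  ``simulate_history``
plants TE families on branches of a dated 19-tip butterfly tree as a
Poisson process, deposits copies in descendant genomes, and converts
insertion ages to divergences under the neutral clock (optionally with
noise and length/age-dependent deletion of old copies).
``simulate_sine_families`` descends SINE copies from master sequences
with subfamily-diagnostic divergence, an embedded LINE-derived 3'
region, and taxon/age-biased poly-A/T tails.  Both serialize their
ground truth alongside the emitted files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .divergence import ClockModel
from .repeat_io import DatedTree, RepeatHit, TEFamily, read_tree

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_tree",
    "DEFAULT_CLADES",
    "simulate_history",
    "simulate_sine_families",
]

# 19-tip fixture mirroring the heliconiine clade structure (outgroups,
# doris, wallacei, erato, sara, melpomene, sylvaniform) with round node
# ages in Myr.  A test fixture, not a published chronogram.
FIXTURE_NEWICK = (
    "(Agraulis_vanillae:26,(Dryas_iulia:22,(Eueides_tales:18,"
    "(((Heliconius_doris:8,(Heliconius_burneyi:4,Heliconius_wallacei:4):4):2,"
    "((((Heliconius_erato:1.5,Heliconius_himera:1.5):0.7,"
    "Heliconius_telesiphe:2.2):0.8,Heliconius_hecalesia:3):4,"
    "(Heliconius_sara:3,Heliconius_demeter:3):4):3):2,"
    "((Heliconius_cydno:3,(Heliconius_melpomene:1.5,Heliconius_timareta:1.5):1.5):3,"
    "((Heliconius_numata:2,Heliconius_besckei:2):2,"
    "(Heliconius_hecale:2,Heliconius_elevatus:2):2):2):6):6):4):4);"
)

DEFAULT_CLADES = {
    "outgroups": {"Agraulis_vanillae", "Dryas_iulia", "Eueides_tales"},
    "doris": {"Heliconius_doris"},
    "wallacei": {"Heliconius_burneyi", "Heliconius_wallacei"},
    "erato": {"Heliconius_erato", "Heliconius_himera",
              "Heliconius_telesiphe", "Heliconius_hecalesia"},
    "sara": {"Heliconius_sara", "Heliconius_demeter"},
    "melpomene": {"Heliconius_cydno", "Heliconius_melpomene",
                  "Heliconius_timareta"},
    "sylvaniform": {"Heliconius_numata", "Heliconius_besckei",
                    "Heliconius_hecale", "Heliconius_elevatus"},
}
DEFAULT_CLADES["erato_sara"] = DEFAULT_CLADES["erato"] | DEFAULT_CLADES["sara"]
DEFAULT_CLADES["melpomene_sylvaniform"] = (
    DEFAULT_CLADES["melpomene"] | DEFAULT_CLADES["sylvaniform"]
)


def default_tree() -> DatedTree:
    tree = read_tree(FIXTURE_NEWICK)
    tree.clades.update({k: frozenset(v) for k, v in DEFAULT_CLADES.items()})
    return tree


#: Mean insertion length (bp) per TE class; SINEs are short, LINEs and
#: LTR elements long, drawn lognormally around these values.
CLASS_LENGTH_BP = {"SINE": 300, "LINE": 2500, "LTR": 3000, "DNA": 800, "RC": 1500}

#: Branch origination rates (families/Myr) per class; of the order of the
#: rates observed on heliconiine terminal branches.
CLASS_ORIGINATION_RATE = {"SINE": 0.25, "LINE": 0.45, "LTR": 0.15,
                          "DNA": 0.20, "RC": 0.05}


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    The clock matches the analysis default (1.9e-9 subs/site/generation,
    4 generations/year, pairwise divergence); origination rates and copy
    counts are set so the fixture tree accumulates a few hundred
    families with realistic class length profiles.
    """

    seed: int
    tree: DatedTree | None = None
    clock: ClockModel = field(default_factory=ClockModel)
    origination_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(CLASS_ORIGINATION_RATE))
    copies_mu: float = 2.5          # lognormal log-mean of copies per tip
    copies_sigma: float = 0.8
    length_sigma: float = 0.35      # lognormal log-sd around class mean length
    divergence_noise_sd: float = 0.0
    deletion_per_bp_myr: float = 2e-6   # hazard scale of old-copy removal
    min_bp_per_tip: int = 0         # when > 0, top up copies so each
                                    # descendant tip carries at least this bp
    genome_size_bp: int = 330_000_000
    genome_size_jitter: float = 0.10
    max_hits: int = 2_000_000
    # SINE master/copy model
    sine_masters: int = 5
    copies_per_master: int = 200
    sine_master_length: int = 300
    master_min_divergence: float = 0.10
    copy_divergence_lo: float = 0.01
    copy_divergence_hi: float = 0.06
    line_tail_length: int = 80
    tail_length_mean: float = 30.0
    tail_length_sd: float = 8.0
    taxa: Sequence[str] = ("Heliconius_erato", "Heliconius_melpomene")
    tail_at_bias: Mapping[str, float] = field(
        default_factory=lambda: {"Heliconius_erato": 0.8,
                                 "Heliconius_melpomene": 0.8})
    # optional stratum-dependent tail bias (P(A) among A/T) for the
    # young-vs-old tail contrast; None disables
    young_tail_at_bias: float | None = None
    old_tail_at_bias: float | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(r < 0 for r in self.origination_rates.values()):
            raise ValueError("origination rates must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    family_branch: dict = field(default_factory=dict)   # family -> branch_id
    family_class: dict = field(default_factory=dict)    # family -> class
    deposited_bp: dict = field(default_factory=dict)    # (species, family) -> bp
    copy_master: dict = field(default_factory=dict)     # copy_id -> master id
    copy_age: dict = field(default_factory=dict)        # copy_id -> age (Myr)

    def to_json(self, path) -> None:
        payload = {
            "family_branch": self.family_branch,
            "family_class": self.family_class,
            "deposited_bp": {f"{sp}\t{fam}": bp
                             for (sp, fam), bp in self.deposited_bp.items()},
            "copy_master": self.copy_master,
            "copy_age": self.copy_age,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gt = cls()
        gt.family_branch = payload["family_branch"]
        gt.family_class = payload["family_class"]
        for key, bp in payload["deposited_bp"].items():
            sp, fam = key.split("\t")
            gt.deposited_bp[(sp, fam)] = bp
        gt.copy_master = payload["copy_master"]
        gt.copy_age = payload["copy_age"]
        return gt


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply n substitutions at distinct random positions."""
    if n_subs <= 0:
        return seq
    chars = list(seq)
    n_subs = min(n_subs, len(chars))
    positions = rng.choice(len(chars), size=n_subs, replace=False)
    for p in positions:
        old = chars[p]
        choices = [b for b in "ACGT" if b != old]
        chars[p] = choices[rng.integers(0, 3)]
    return "".join(chars)


def simulate_history(config: SimConfig):
    """Plant TE families on tree branches and emit per-species hit tables.

    Families arise on each branch as a Poisson process with the per-class
    rate; every family deposits copies in all tips descending from its
    branch.  Copy insertion ages are uniform on (0, family origin time);
    divergence = lineage_factor * mu * generations_per_year * age_years
    plus optional truncated Gaussian noise.  Old, long copies are thinned
    with probability 1 - exp(-hazard * length_bp * age_myr).

    Returns (hits_by_species, genome_sizes, ground_truth).
    """
    tree = config.tree or default_tree()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    hits_by_species: dict[str, list[RepeatHit]] = {sp: [] for sp in tree.tip_labels}
    cursor = {sp: 1 for sp in tree.tip_labels}
    rate_per_year = config.clock.subs_per_site_per_year

    fam_idx = 0
    n_hits = 0
    for branch in tree.branches():
        for cls, rate in sorted(config.origination_rates.items()):
            n_fams = rng.poisson(rate * branch.duration_myr)
            for _ in range(n_fams):
                fam_idx += 1
                fam = f"Fam{fam_idx:04d}_{cls}"
                origin_myr = float(rng.uniform(branch.child_age, branch.parent_age))
                truth.family_branch[fam] = branch.branch_id
                truth.family_class[fam] = cls
                mean_len = CLASS_LENGTH_BP[cls]
                for sp in sorted(branch.tips):
                    n_copies = max(1, int(round(float(
                        rng.lognormal(config.copies_mu, config.copies_sigma)))))
                    deposited = 0
                    copies: list[tuple[int, float]] = []
                    for _ in range(n_copies):
                        length = max(50, int(round(float(rng.lognormal(
                            math.log(mean_len), config.length_sigma)))))
                        age = float(rng.uniform(0.0, origin_myr))
                        if config.deletion_per_bp_myr > 0:
                            p_del = 1.0 - math.exp(
                                -config.deletion_per_bp_myr * length * age)
                            if rng.random() < p_del:
                                continue
                        copies.append((length, age))
                    if config.min_bp_per_tip > 0:
                        while sum(l for l, _ in copies) < config.min_bp_per_tip:
                            length = max(50, int(round(float(rng.lognormal(
                                math.log(mean_len), config.length_sigma)))))
                            copies.append((length,
                                           float(rng.uniform(0.0, origin_myr))))
                    for length, age in copies:
                        d = rate_per_year * age * 1e6
                        if config.divergence_noise_sd > 0:
                            d = max(0.0, d + float(
                                rng.normal(0.0, config.divergence_noise_sd)))
                        d = min(d, 1.0)
                        start = cursor[sp]
                        hit = RepeatHit(
                            species_id=sp, scaffold="scaf1", start=start,
                            end=start + length - 1,
                            strand="+" if rng.random() < 0.5 else "-",
                            family_name=fam, class_label=cls, divergence=d,
                        )
                        cursor[sp] = start + length + 10
                        hits_by_species[sp].append(hit)
                        deposited += length
                        n_hits += 1
                        if n_hits > config.max_hits:
                            raise ValueError(
                                "simulated hit table exceeds configured cap"
                            )
                    if deposited > 0:
                        truth.deposited_bp[(sp, fam)] = deposited

    genomes = {}
    for sp in sorted(tree.tip_labels):
        jitter = rng.uniform(-config.genome_size_jitter,
                             config.genome_size_jitter)
        genomes[sp] = int(config.genome_size_bp * (1.0 + jitter))
    return hits_by_species, genomes, truth


def simulate_sine_families(config: SimConfig):
    """Descend SINE copies from divergent masters with poly-A/T tails.

    K master sequences with enforced pairwise divergence carry a shared
    LINE-derived 3' region (distinct partner LINE per master).  Each copy
    is a mutated master (planted divergence uniform in the configured
    range) plus a tail of taxon-biased A/T composition; when the
    stratum-dependent biases are set, copies below/above the 0.05
    divergence cutoff draw tail bases with the young/old bias instead.

    Returns (copies, references, line_library, ground_truth) where copies
    are (copy_id, species_id, divergence, sequence) tuples and references
    are (name, master sequence) pairs.
    """
    if config.sine_masters < 1:
        raise ValueError("need at least one master")
    rng = np.random.default_rng(config.seed)
    K = config.sine_masters
    L = config.sine_master_length
    tail_len_of_line = config.line_tail_length

    lines = []
    for i in range(K):
        lines.append(TEFamily(name=f"LINE{i+1:02d}", class_label="LINE",
                              superfamily="RTE",
                              consensus=_random_seq(rng, 600)))

    masters: list[str] = []
    min_diff = int(math.ceil(config.master_min_divergence * L))
    for i in range(K):
        for attempt in range(200):
            head = _random_seq(rng, L - tail_len_of_line)
            cand = head + lines[i].consensus[-tail_len_of_line:]
            ok = True
            for m in masters:
                diff = sum(1 for a, b in zip(cand, m) if a != b)
                if diff < min_diff:
                    ok = False
                    break
            if ok:
                masters.append(cand)
                break
        else:
            raise ValueError("could not satisfy master pairwise-divergence floor")

    truth = GroundTruth()
    copies: list[tuple] = []
    taxa = list(config.taxa)
    rate_per_year = config.clock.subs_per_site_per_year
    for i, master in enumerate(masters):
        master_id = f"Master{i+1:02d}"
        for c in range(config.copies_per_master):
            copy_id = f"{master_id}_c{c+1:04d}"
            sp = taxa[int(rng.integers(0, len(taxa)))]
            d = float(rng.uniform(config.copy_divergence_lo,
                                  config.copy_divergence_hi))
            n_subs = int(rng.poisson(d * L))
            body = _mutate(rng, master, n_subs)
            tail_len = max(5, int(round(float(
                rng.normal(config.tail_length_mean, config.tail_length_sd)))))
            p_a = config.tail_at_bias.get(sp, 0.8)
            if config.young_tail_at_bias is not None and d < 0.05:
                p_a = config.young_tail_at_bias
            elif config.old_tail_at_bias is not None and d >= 0.05:
                p_a = config.old_tail_at_bias
            tail = "".join("A" if rng.random() < p_a else "T"
                           for _ in range(tail_len))
            copies.append((copy_id, sp, d, body + tail))
            truth.copy_master[copy_id] = master_id
            truth.copy_age[copy_id] = d / rate_per_year / 1e6
    references = [(f"Master{i+1:02d}", m) for i, m in enumerate(masters)]
    return copies, references, lines, truth
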