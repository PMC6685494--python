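"""End-to-end orchestration on a single config.

Runs simulate -> proportion summaries -> origination rates ->
SINE subfamilies -> partners/tails -> genome-size stats in dependency
order, logging stage timings to stderr and writing a manifest with a
content checksum for every output file.  Each stage is also runnable
standalone through its module (or the CLI), which is what the tests
exercise; the pipeline just wires them together.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd

from . import accumulation, lineage_rates, phylo_stats, sine_partners, sine_subfamilies
from .divergence import AgeClass
from .repeat_io import write_fasta, write_genome_table, write_hits_tsv, write_rm_out
from .synthetic_data import SimConfig, default_tree, simulate_history, simulate_sine_families

__all__ = ["run_pipeline", "RunConfigError"]

_ALLOWED_KEYS = {"seed", "out_dir", "simulate", "sine", "rates", "stats"}
_ALLOWED_SIM = {"origination_rates", "copies_mu", "copies_sigma",
                "divergence_noise_sd", "deletion_per_bp_myr",
                "min_bp_per_tip", "genome_size_bp", "genome_size_jitter"}
_ALLOWED_SINE = {"sine_masters", "copies_per_master", "copy_divergence_lo",
                 "copy_divergence_hi", "taxa", "gamma"}


class RunConfigError(ValueError):
    pass


def _validate(config: dict) -> None:
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise RunConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise RunConfigError("config requires a seed")
    if "out_dir" not in config:
        raise RunConfigError("config requires out_dir")
    for key, allowed in (("simulate", _ALLOWED_SIM), ("sine", _ALLOWED_SINE)):
        block = config.get(key, {})
        bad = set(block) - allowed
        if bad:
            raise RunConfigError(f"unknown keys in {key!r} block: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute all stages; return the output manifest (also written to disk)."""
    _validate(config)
    seed = int(config["seed"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    timings: dict[str, float] = {}

    def _stage(name):
        def wrapper(fn):
            t0 = time.perf_counter()
            print(f"[tedyn] stage {name} ...", file=sys.stderr)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            print(f"[tedyn] stage {name} done in {timings[name]:.1f}s",
                  file=sys.stderr)
        return wrapper

    sim_kwargs = dict(config.get("simulate", {}))
    sim = SimConfig(seed=seed, **sim_kwargs)
    tree = default_tree()
    state: dict = {}

    @_stage("simulate")
    def _():
        hits, genomes, truth = simulate_history(sim)
        hits_dir = out_dir / "hits"
        hits_dir.mkdir(exist_ok=True)
        for sp, sp_hits in sorted(hits.items()):
            p = hits_dir / f"{sp}.out"
            write_rm_out(sp_hits, p)
            outputs.append(p)
        write_genome_table(genomes, out_dir / "genomes.tsv")
        truth.to_json(out_dir / "truth.json")
        (out_dir / "tree.nwk").write_text(
            tree.as_dendropy().as_string(schema="newick"))
        outputs.extend([out_dir / "genomes.tsv", out_dir / "truth.json",
                        out_dir / "tree.nwk"])
        state.update(hits=hits, genomes=genomes, truth=truth)

    @_stage("proportions")
    def _():
        for group_by in ("class", "family"):
            for stratum in ("recent", "old", "all"):
                table = accumulation.proportion_table(
                    state["hits"], state["genomes"], group_by=group_by,
                    stratum=stratum, age_class=AgeClass())
                p = out_dir / f"proportions_{group_by}_{stratum}.tsv"
                table.to_csv(p, sep="\t")
                outputs.append(p)

    @_stage("rates")
    def _():
        presence = lineage_rates.presence_matrix(state["hits"])
        assignment = lineage_rates.assign_branch(presence, tree)
        fam_classes = {fam: fam.rsplit("_", 1)[1]
                       for fam in presence.families}
        rates = lineage_rates.origination_rates(assignment, tree, fam_classes)
        presence.scores.to_csv(out_dir / "presence.tsv", sep="\t")
        presence.bp.to_csv(out_dir / "presence_bp.tsv", sep="\t")
        pd.DataFrame(
            [{"family_name": f, "branch_id": b, "reason": ""}
             for f, b in sorted(assignment.assigned.items())] +
            [{"family_name": f, "branch_id": "", "reason": r}
             for f, r in sorted(assignment.unassigned.items())]
        ).to_csv(out_dir / "assignments.tsv", sep="\t", index=False)
        rates.to_csv(out_dir / "rates.tsv", sep="\t")
        outputs.extend([out_dir / "presence.tsv", out_dir / "presence_bp.tsv",
                        out_dir / "assignments.tsv", out_dir / "rates.tsv"])

    sine_kwargs = dict(config.get("sine", {}))
    # at the synthetic scale (hundreds of copies, score-weighted edges) the
    # useful resolution is far below the genome-scale setting of 59: the
    # configuration-model null term grows with total graph weight
    gamma = float(sine_kwargs.pop("gamma", 1.0))
    sine_cfg = SimConfig(seed=seed + 1, **sine_kwargs)

    @_stage("subfamilies")
    def _():
        copies, refs, lines, truth = simulate_sine_families(sine_cfg)
        cores, _discard = sine_subfamilies.trim_to_core(
            [(cid, sp, seq) for cid, sp, _d, seq in copies], refs)
        net = sine_subfamilies.build_network(cores)
        part = sine_subfamilies.detect_communities(
            net, gamma=gamma, seed=seed,
            species_of={c.copy_id: c.species_id for c in cores})
        part = sine_subfamilies.community_consensus(part, cores, seed=seed)
        part = sine_subfamilies.merge_identical(part, cores, seed=seed)
        clusters = sine_subfamilies.cluster_subfamilies(
            sorted(part.consensus.items()))
        write_fasta([(c.copy_id, c.sequence) for c in cores],
                    out_dir / "cores.fasta")
        pd.DataFrame(
            [{"copy_a": net.nodes[i], "copy_b": net.nodes[j], "weight": w}
             for (i, j), w in sorted(net.edges.items())]
        ).to_csv(out_dir / "network.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"copy_id": cid, "community": c}
             for cid, c in sorted(part.membership.items())]
        ).to_csv(out_dir / "partition.tsv", sep="\t", index=False)
        write_fasta([(f"subfam{cid}", cons)
                     for cid, cons in sorted(part.consensus.items())],
                    out_dir / "consensus.fasta")
        pd.DataFrame(
            [{"subfamily": f"subfam{n}", "cluster": f"subfam{c}"}
             for n, c in sorted(clusters.items())]
        ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        outputs.extend([out_dir / "cores.fasta", out_dir / "network.tsv",
                        out_dir / "partition.tsv", out_dir / "consensus.fasta",
                        out_dir / "clusters.tsv"])
        state.update(sine_copies=copies, sine_refs=refs, sine_lines=lines)

    @_stage("partners")
    def _():
        from .repeat_io import TEFamily
        calls = []
        for name, master in state["sine_refs"]:
            sine = TEFamily(name=name, class_label="SINE", superfamily="Metulj",
                            consensus=master)
            call = sine_partners.find_partner(sine, state["sine_lines"])
            calls.append({"sine_family": call.sine_family,
                          "line_family": call.line_family or "",
                          "identity": call.identity,
                          "aligned_bp": call.aligned_bp,
                          "score": call.score})
        pd.DataFrame(calls).to_csv(out_dir / "partners.tsv", sep="\t",
                                   index=False)
        profiles = sine_partners.tail_composition(
            state["sine_copies"], state["sine_refs"][0][1], seed=seed)
        rows = []
        for pr in profiles:
            row = {"species_id": pr.species_id, "stratum": pr.stratum,
                   "replicate": pr.replicate, "n_copies": pr.n_copies,
                   "empty": pr.empty, **pr.counts}
            row.update(pr.all_ratios())
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "tails.tsv", sep="\t", index=False)
        outputs.extend([out_dir / "partners.tsv", out_dir / "tails.tsv"])

    @_stage("stats")
    def _():
        genomes = state["genomes"]
        te_per_bp = {
            sp: sum(h.length_bp for h in sp_hits) / genomes[sp]
            for sp, sp_hits in state["hits"].items()
        }
        gsize = {sp: float(genomes[sp]) for sp in genomes}
        rows = []
        for label, use_tree in (("ols", None), ("pic", tree)):
            res = phylo_stats.genome_size_model(gsize, te_per_bp, tree=use_tree)
            rows.append({"model": label, "slope": res.slope,
                         "intercept": res.intercept, "r_squared": res.r_squared,
                         "pvalue": res.pvalue, "df": res.df})
        pd.DataFrame(rows).to_csv(out_dir / "genome_size_models.tsv",
                                  sep="\t", index=False)
        outputs.append(out_dir / "genome_size_models.tsv")

    manifest = {
        "seed": seed,
        "stage_seconds": timings,
        "files": {str(p.relative_to(out_dir)): _sha256(p)
                  for p in sorted(set(outputs))},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
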