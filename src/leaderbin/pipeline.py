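"""End-to-end demo pipeline: simulate → reference bins → evaluate → compare.

Mirrors the two-part leaderboard workflow: (1) build internal reference
genome bins from high-accuracy long-read-style contigs of the community
itself, scored and selected with the bin-score equation; (2) emulate
short-read assemblies under library-chemistry coverage presets and
evaluate them against those references; then (3) compare per-sample vs
pooled differential-coverage binning on the fragmented contigs and
(4) dereplicate the pooled bin sets with winner tallies. A plate-design
sheet and a JSON manifest (all parameters and derived seeds) round out
the run directory.

Every stage derives its seed from the top-level seed and the stage name,
and every writer is byte-stable, so a rerun with the same config
reproduces the run directory verbatim.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, binscore, derep, indexes, refeval, simdata
from . import io as lio
from .core import ContigSet

ASSEMBLY_PRESETS = {
    # (bias_profile, sub_rate, indel_rate): ligation-like libraries get
    # uniform coverage; transposase-like libraries get GC bias, dropout
    # windows and a higher indel rate.
    "ligation": ("uniform", 2e-4, 2e-5),
    "transposase": ("transposase", 2e-4, 2e-4),
}


@dataclass
class RunConfig:
    """Demo-scale run parameters; defaults are the standard conditions."""

    seed: int = 0
    n_genomes: int = 10
    genome_length: int = 500_000
    m_markers: int = 40
    marker_len: int = 300
    gc_min: float = 0.35
    gc_max: float = 0.65
    n_samples: int = 12
    sigma_log: float = 1.0
    rho: float = 0.5
    total_depth: float = 300.0
    tslr_segment_min: int = 3000
    tslr_segment_max: int = 10000
    tslr_error_rate: float = 0.001
    break_depth: float = 2.0
    smooth_window: int = 100
    min_contig: int = 500
    top_k_refs: int = 5
    min_ref_completeness: float = 0.85
    binning_min_len: int = 1000
    binning_k_max: int = 16
    subsample_n: int = 10_000_000
    origin_sample: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages into ``outdir``; returns the run directory.

    Deterministic and idempotent: every stage is recomputed from the
    config, so reruns (including after deleting intermediates) emit
    byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    seeds = {stage: lio.derive_seed(cfg.seed, stage)
             for stage in ("genomes", "abundance", "tslr", "refbin",
                           "assembly", "binning", "derep")}

    # ---- stage 1: community simulation
    gcs = np.linspace(cfg.gc_min, cfg.gc_max, cfg.n_genomes)
    genomes = simdata.generate_genomes(
        cfg.n_genomes, cfg.genome_length, cfg.m_markers, cfg.marker_len,
        gc=gcs, seed=seeds["genomes"])
    gmap = {g.id: g for g in genomes}
    abundance = simdata.sample_abundances(
        cfg.n_genomes, cfg.n_samples, cfg.sigma_log, cfg.rho,
        seed=seeds["abundance"], genome_ids=[g.id for g in genomes])
    lio.write_genomes(genomes, out / "genomes.fasta", out / "markers.tsv")
    lio.write_abundance(abundance, out / "abundance.tsv")

    # ---- stage 2: long-read-style reference contigs (with noisy depths)
    depths = simdata.community_depths(abundance, cfg.total_depth)
    tslr = simdata.emulate_tslr_bins(
        genomes, (cfg.tslr_segment_min, cfg.tslr_segment_max),
        cfg.tslr_error_rate, seed=seeds["tslr"], depths=depths,
        depth_noise=True)
    tslr_all = ContigSet([c for g in genomes for c in tslr[g.id]])
    lio.write_contigset(tslr_all, out / "tslr_contigs.fasta", out / "tslr_contigs.tsv")

    # ---- stage 3: reference-bin construction (bin, score, select top-k)
    assign = binning.bin_contigs(
        tslr_all, mode=binning.PER_SAMPLE,
        k_range=(2, min(cfg.binning_k_max, len(tslr_all))),
        seed=seeds["refbin"], min_len=cfg.binning_min_len)
    quals = binscore.assess_bins(assign.labels, tslr_all, gmap, cfg.m_markers,
                                 origin_sample=cfg.origin_sample)
    qrows = [{"bin_id": q.bin_id, "C": q.C, "R": q.R, "A": q.A,
              "A_max": q.A_max, "score": q.score, "tier": q.tier}
             for q in quals]
    pd.DataFrame(qrows).to_csv(out / "tslr_bin_quality.tsv", sep="\t",
                               index=False, float_format=lio.FLOAT_FORMAT)
    selected, short = binscore.select_reference_bins(
        quals, k=cfg.top_k_refs, min_completeness=cfg.min_ref_completeness)
    members = assign.bin_members()
    ref_bins: dict[str, ContigSet] = {}
    refdir = out / "reference_bins"
    refdir.mkdir(exist_ok=True)
    for bid in selected:
        cs = tslr_all.subset(members[bid])
        ref_bins[bid] = cs
        lio.write_fasta(refdir / f"{bid}.fasta", ((c.id, c.sequence) for c in cs))
    lio.write_json({"selected": selected, "short_of_k": short},
                   out / "selected_refs.json")

    # ---- stage 4: emulated short-read assemblies per chemistry preset
    assemblies: dict[str, ContigSet] = {}
    for preset, (profile, sub_rate, indel_rate) in ASSEMBLY_PRESETS.items():
        contigs = ContigSet()
        for i, g in enumerate(genomes):
            fld = simdata.simulate_coverage(
                g, abundance.values[i, cfg.origin_sample], cfg.total_depth,
                bias_profile=profile,
                seed=lio.derive_seed(seeds["assembly"], f"{preset}:{g.id}"))
            cs = simdata.emulate_assembly(
                g, fld, break_depth=cfg.break_depth, sub_rate=sub_rate,
                indel_rate=indel_rate, min_contig=cfg.min_contig,
                seed=lio.derive_seed(seeds["assembly"], f"{preset}:{g.id}:err"),
                id_prefix=f"{preset}_{g.id}_c", smooth_window=cfg.smooth_window)
            for c in cs:
                contigs.add(c)
        assemblies[preset] = contigs
        lio.write_contigset(contigs, out / f"assembly_{preset}.fasta",
                            out / f"assembly_{preset}.tsv")

    # ---- stage 5: reference-based evaluation
    eval_rows = []
    for preset, contigs in assemblies.items():
        for bid in selected:
            rep = refeval.evaluate_assembly(contigs, ref_bins[bid],
                                            ref_name=bid,
                                            min_len=cfg.min_contig)
            row = {"preset": preset, **rep.to_dict()}
            eval_rows.append(row)
    eval_df = pd.DataFrame(eval_rows)
    eval_df.to_csv(out / "eval_report.tsv", sep="\t", index=False,
                   float_format=lio.FLOAT_FORMAT)
    lio.write_json({"reports": eval_rows}, out / "eval_report.json")

    # abundance-stratified per-reference-contig recovery (both presets)
    for preset, contigs in assemblies.items():
        rows = refeval.fraction_vs_abundance(
            contigs, tslr_all,
            depth_proxy=[float(c.depths[cfg.origin_sample]) for c in tslr_all],
            min_len=cfg.min_contig)
        pd.DataFrame(rows, columns=["ref_contig", "depth", "fraction"]).to_csv(
            out / f"fraction_vs_depth_{preset}.tsv", sep="\t", index=False,
            float_format=lio.FLOAT_FORMAT)

    # ---- stage 6: binning-mode comparison on the fragmented contigs
    cmp = binning.compare_modes(
        tslr_all, gmap, cfg.m_markers,
        k_range=(2, min(cfg.binning_k_max, len(tslr_all))),
        seed=seeds["binning"], min_len=cfg.binning_min_len)
    mode_summary = {
        "delta_completeness": cmp["delta_completeness"],
        "delta_contamination": cmp["delta_contamination"],
        "per_sample": {"ari": cmp["modes"]["per_sample"]["ari"],
                       "k": cmp["modes"]["per_sample"]["k"]},
        "pooled": {"ari": cmp["modes"]["pooled"]["ari"],
                   "k": cmp["modes"]["pooled"]["k"]},
    }
    lio.write_json(mode_summary, out / "mode_comparison.json")
    for mode in (binning.PER_SAMPLE, binning.POOLED):
        m = cmp["modes"][mode]
        pd.DataFrame(
            [{"contig_id": cid, "bin_id": bid}
             for cid, bid in sorted(m["assignment"].labels.items())]
        ).to_csv(out / f"bins_{mode}.tsv", sep="\t", index=False)
        m["bin_table"].reset_index().to_csv(
            out / f"bin_metrics_{mode}.tsv", sep="\t", index=False,
            float_format=lio.FLOAT_FORMAT)

    # ---- stage 7: dereplication of bins pooled across the two modes
    pooled_bins: dict[str, ContigSet] = {}
    origins: dict[str, str] = {}
    qual_map: dict[str, tuple[float, float]] = {}
    lengths: dict[str, int] = {}
    for mode in (binning.PER_SAMPLE, binning.POOLED):
        m = cmp["modes"][mode]
        for bid, cids in m["assignment"].bin_members().items():
            name = f"{mode}.{bid}"
            cs = tslr_all.subset(cids)
            pooled_bins[name] = cs
            origins[name] = mode
            row = m["bin_table"].loc[bid]
            qual_map[name] = (float(row["completeness"]), float(row["contamination"]))
            lengths[name] = cs.total_length()
    clusters = derep.cluster_bins(pooled_bins)
    winners = []
    cluster_rows = []
    for ci, cluster in enumerate(clusters):
        cid = f"cluster{ci:03d}"
        rows = [(b, qual_map[b][0], qual_map[b][1], lengths[b]) for b in cluster]
        w = derep.pick_winner(rows, origins, cluster_id=cid)
        winners.append(w)
        for b in cluster:
            cluster_rows.append({"cluster_id": cid, "member": b,
                                 "origin": origins[b],
                                 "winner": int(b == w.winner_bin)})
    pd.DataFrame(cluster_rows).to_csv(out / "derep_clusters.tsv", sep="\t",
                                      index=False)
    tally = derep.tally_origins(winners, qual_map)
    lio.write_json({"n_clusters": len(clusters), "tally": tally},
                   out / "derep_tally.json")

    # ---- stage 8: plate design sheet
    plate = indexes.build_plate(0)
    pd.DataFrame(indexes.plate_rows(plate)).to_csv(out / "plate0.csv", index=False)

    # ---- manifest
    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "n_tslr_contigs": len(tslr_all),
        "n_selected_refs": len(selected),
        "presets": {p: {"bias_profile": v[0], "sub_rate": v[1],
                        "indel_rate": v[2]} for p, v in ASSEMBLY_PRESETS.items()},
    }
    lio.write_json(manifest, out / "manifest.json")
    return out
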