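"""Composed analysis pipeline: profiles → recoding → malleability →
enrichment → codon-usage geometry, chained on disk.

``pipeline_run`` takes one config mapping (typically loaded from YAML),
derives every stage's randomness from the single manifest seed, writes each
stage's outputs as TSV/FASTA into the output directory and emits a
``manifest.json``.  A rerun with an unchanged config digest skips stages
whose outputs already exist.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import codon_usage, enrichment, malleability, synthetic
from .errors import ConfigError
from .io import RunManifest, read_annotations, validate_pairs, write_fasta
from .profiles import PropensityScale, SequencePair, native_r
from .recoding import RecodingConfig, transcriptome_sweep

log = logging.getLogger("pyrmatch")

STAGES = ("profile", "steer", "random", "malleability", "enrich", "usage", "mds")


def _load_scale(config: dict) -> PropensityScale:
    path = config.get("scale")
    if path:
        return PropensityScale.from_tsv(path)
    return PropensityScale.polar_requirement()


def _load_pairs(config: dict, outdir: Path) -> tuple[list[SequencePair], pd.DataFrame]:
    inputs = config.get("inputs") or {}
    if "protein_fasta" in inputs and "cds_fasta" in inputs:
        return validate_pairs(inputs["protein_fasta"], inputs["cds_fasta"])
    sim = config.get("simulate") or {}
    cfg = synthetic.GeneratorConfig(
        n_pairs=int(sim.get("n_pairs", 50)),
        min_length=int(sim.get("min_length", 120)),
        max_length=int(sim.get("max_length", 300)),
        target_r=sim.get("target_r"),
        tolerance=float(sim.get("tolerance", 0.05)),
        seed=int(config.get("seed", 0)),
    )
    scale = _load_scale(config)
    pairs = synthetic.generate_pairs(cfg, scale)
    write_fasta(outdir / "simulated_proteins.fasta", [(p.id, p.protein) for p in pairs])
    write_fasta(outdir / "simulated_cds.fasta", [(p.id, p.full_cds()) for p in pairs])
    return pairs, pd.DataFrame(columns=["id", "reason"])


def pipeline_run(config: dict, outdir) -> Path:
    """Run the configured stage list; returns the output directory.

    Stage outputs downstream stages need must be requested (or already on
    disk): e.g. ``malleability`` requires the ``steer`` table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages") or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s) {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    manifest = RunManifest(command="pipeline", config=config, seed=seed)

    # resume: identical config digest -> stages with outputs present are skipped
    prev_digest = None
    mpath = outdir / "manifest.json"
    if mpath.exists():
        try:
            prev_digest = json.loads(mpath.read_text()).get("config_digest")
        except (json.JSONDecodeError, OSError):
            prev_digest = None
    resume = prev_digest == manifest.config_digest()

    def fresh(*names: str) -> bool:
        missing = [n for n in names if not (outdir / n).exists()]
        if resume and not missing:
            log.info("skipping stage; outputs %s present", names)
            return False
        return True

    scale = _load_scale(config)
    pairs, excluded = _load_pairs(config, outdir)
    excluded.to_csv(outdir / "excluded.tsv", sep="\t", index=False)
    log.info("%d validated pairs, %d excluded", len(pairs), len(excluded))
    if not pairs:
        raise ConfigError("no validated pairs to analyze")
    rec_cfg = RecodingConfig(
        n_steps=int((config.get("recoding") or {}).get("n_steps", 10_000)),
        seed=seed,
    )
    out: list[str] = []

    if "profile" in stages and fresh("profiles.tsv"):
        rows = []
        for p in pairs:
            rows.append({"id": p.id, "length": len(p.protein),
                         "r_native": native_r(p, scale)})
        pd.DataFrame(rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
        out.append("profiles.tsv")

    sweep_table: Optional[pd.DataFrame] = None
    if "steer" in stages and fresh("malleability.tsv", "best.fasta", "worst.fasta"):
        sweep = transcriptome_sweep(pairs, scale, rec_cfg)
        sweep_table = sweep.table
        cols = ["id", "r_native", "r_best", "r_worst", "delta_r", "n_eligible"]
        sweep.table[cols].to_csv(outdir / "malleability.tsv", sep="\t", index=False)
        write_fasta(outdir / "best.fasta",
                    list(zip(sweep.table["id"], sweep.table["best_cds"])))
        write_fasta(outdir / "worst.fasta",
                    list(zip(sweep.table["id"], sweep.table["worst_cds"])))
        sweep.summary().to_csv(outdir / "sweep_summary.tsv", sep="\t")
        out += ["malleability.tsv", "best.fasta", "worst.fasta", "sweep_summary.tsv"]
    elif (outdir / "malleability.tsv").exists():
        sweep_table = pd.read_csv(outdir / "malleability.tsv", sep="\t")

    if "random" in stages and fresh("random_summary.tsv"):
        n_variants = int((config.get("recoding") or {}).get("n_variants", 100))
        res = transcriptome_sweep(
            pairs, scale,
            RecodingConfig(direction="none", seed=seed), n_variants=n_variants,
        )
        res.table.to_csv(outdir / "random_summary.tsv", sep="\t", index=False)
        out.append("random_summary.tsv")

    tails: Optional[tuple[list[str], list[str]]] = None
    if "malleability" in stages:
        if sweep_table is None:
            raise ConfigError("malleability stage requires the steer stage output")
        if fresh("tails.tsv", "malleability_stats.json"):
            frac = float((config.get("malleability") or {}).get("tail_fraction", 0.05))
            low, high = malleability.tail_sets(sweep_table, frac)
            tails = (low, high)
            pd.DataFrame(
                [{"id": i, "tail": "low"} for i in low]
                + [{"id": i, "tail": "high"} for i in high]
            ).to_csv(outdir / "tails.tsv", sep="\t", index=False)
            rho, p = malleability.native_vs_malleability(sweep_table)
            (outdir / "malleability_stats.json").write_text(
                json.dumps({"spearman_rho": rho, "spearman_p": p}, indent=2) + "\n"
            )
            out += ["tails.tsv", "malleability_stats.json"]

    if "enrich" in stages:
        if sweep_table is None:
            raise ConfigError("enrich stage requires the steer stage output")
        ann_path = (config.get("inputs") or {}).get("annotations")
        if ann_path:
            ann = read_annotations(ann_path)
        else:
            plan = [
                synthetic.AnnotationTerm(**t)
                for t in (config.get("simulate") or {}).get("annotation_plan", [])
            ]
            gen_cfg = synthetic.GeneratorConfig(
                n_pairs=max(len(pairs), 1), annotation_plan=plan, seed=seed
            )
            ann = synthetic.generate_annotations(gen_cfg, sweep_table)
            ann.to_csv(outdir / "simulated_annotations.tsv", sep="\t", index=False)
        if fresh("enrichment_low.tsv", "enrichment_high.tsv") and len(ann):
            if tails is None:
                frac = float((config.get("malleability") or {}).get("tail_fraction", 0.05))
                tails = malleability.tail_sets(sweep_table, frac)
            background = sweep_table["id"].tolist()
            alpha = float((config.get("enrich") or {}).get("alpha", 0.01))
            for name, subset in zip(("low", "high"), tails):
                rep = enrichment.enrich_report(subset, background, ann, alpha)
                rep.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
                out.append(f"enrichment_{name}.tsv")

    vectors = None
    if "usage" in stages or "mds" in stages:
        if sweep_table is None:
            raise ConfigError("usage/mds stages require the steer stage output")
        vectors = [
            codon_usage.standard_code_usage(),
            codon_usage.usage_vector([p.cds for p in pairs], "native"),
            codon_usage.usage_vector(sweep_table["best_cds"], "best")
            if "best_cds" in sweep_table
            else codon_usage.usage_vector(list(read_fasta_vals(outdir / "best.fasta")), "best"),
            codon_usage.usage_vector(sweep_table["worst_cds"], "worst")
            if "worst_cds" in sweep_table
            else codon_usage.usage_vector(list(read_fasta_vals(outdir / "worst.fasta")), "worst"),
        ]
    if "usage" in stages and fresh("usage.tsv", "usage_distances.tsv"):
        pd.DataFrame([v.as_series() for v in vectors]).to_csv(
            outdir / "usage.tsv", sep="\t"
        )
        dm = codon_usage.distance_matrix(vectors)
        dm.to_frame().to_csv(outdir / "usage_distances.tsv", sep="\t")
        shifts = codon_usage.worst_to_best_shifts(vectors[3], vectors[2])
        shifts.to_csv(outdir / "usage_shifts.tsv", sep="\t", index=False)
        out += ["usage.tsv", "usage_distances.tsv", "usage_shifts.tsv"]
    if "mds" in stages and fresh("mds_embedding.tsv", "mds_variance.tsv"):
        dm = codon_usage.distance_matrix(vectors)
        dims = min(3, len(vectors) - 1)
        coords, varfrac = codon_usage.classical_mds(dm, dims=dims)
        pd.DataFrame(
            coords, index=dm.labels,
            columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
        ).to_csv(outdir / "mds_embedding.tsv", sep="\t")
        pd.DataFrame({
            "dims": np.arange(1, varfrac.size + 1),
            "variance_fraction": varfrac,
        }).to_csv(outdir / "mds_variance.tsv", sep="\t", index=False)
        out += ["mds_embedding.tsv", "mds_variance.tsv"]

    manifest.outputs = sorted(set(out))
    manifest.write(mpath)
    return outdir


def read_fasta_vals(path):
    from .io import read_fasta

    return read_fasta(path).values()
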