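"""End-to-end orchestration: genotypes + metadata -> full report bundle.

Stage order mirrors the analysis workflow: completeness filter -> diversity
battery -> compositional differentiation at three integration levels with
both permutation analyses -> cluster inference (replicated K-means/deltaK,
then DAPC memberships) -> MAWP rule engine. Every output file is plain TSV,
CSV or JSON; the manifest records the seed and a hash of the configuration
so that re-running with the same inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, differentiation, diversity, selection
from .genotypes import (
    PopulationFrame,
    filter_complete_individuals,
    read_genepop,
    read_metadata,
)

log = logging.getLogger("deltapop")


def bundled_population_metadata() -> pd.DataFrame:
    """The packaged attribute table for the 27 German survey populations.

    Encodes each site's region (N/S), eco-geographic unit, ecological form,
    size class, management/protection/threat flags and the published
    gene-pool Delta_j, as used by the MAWP rule engine.
    """
    with resources.as_file(
        resources.files("deltapop.data") / "german_populations.csv"
    ) as p:
        return read_metadata(p)


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    genotypes: str | None = None
    metadata: str | None = None
    out_dir: str = "deltapop_out"
    seed: int = 0
    rare_threshold: float = 0.05
    rarefaction_individuals: int | None = None
    hwe_permutations: int = 10_000
    levels: tuple[str, ...] = differentiation.LEVELS
    permutations: int = 1000
    aggregation: str = "mean"
    weighted: bool = True
    k_range: tuple[int, int] = (2, 6)
    cluster_runs: int = 100
    kmeans_starts: int = 5
    kmeans_iters: int = 50_000
    run_hwe: bool = False
    skip_genetics: bool = False
    selection: selection.SelectionConfig = field(
        default_factory=selection.SelectionConfig
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sel = raw.pop("selection", None)
        cfg = cls(**raw)
        if sel:
            cfg.selection = selection.SelectionConfig(**sel)
        for attr in ("levels", "k_range"):
            setattr(cfg, attr, tuple(getattr(cfg, attr)))
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed and the stage name."""
        crc = zlib.crc32(stage.encode())
        return int(
            np.random.SeedSequence([self.seed, crc]).generate_state(1)[0] % (2**31)
        )


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``). A stage
    failure aborts with the stage name; outputs of completed stages remain
    on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
        "outputs": [],
    }

    meta = None
    if cfg.metadata:
        meta = read_metadata(cfg.metadata)

    gene_pool_delta = None
    stage = "load"
    try:
        if not cfg.skip_genetics:
            if cfg.genotypes is None:
                raise ValueError("genotypes path is required unless skip_genetics")
            gm, pf = read_genepop(cfg.genotypes)
            if meta is not None:
                pf = pf.with_metadata(meta)
            log.info("loaded %d individuals x %d loci", gm.n_individuals, gm.n_loci)

            stage = "filter"
            gm, report = filter_complete_individuals(gm)
            pf = pf.subset(gm.individual_ids)
            report.to_tsv(out / "exclusions.tsv")
            manifest["outputs"].append("exclusions.tsv")
            manifest["stages"].append({"stage": stage, "excluded": report.n_excluded,
                                       "retained": gm.n_individuals})

            stage = "diversity"
            dcfg = diversity.DiversityConfig(
                rare_threshold=cfg.rare_threshold,
                rarefaction_individuals=cfg.rarefaction_individuals,
                hwe_permutations=cfg.hwe_permutations,
                rng_seed=cfg.stage_seed("diversity"),
            )
            summary = diversity.diversity_summary(gm, pf, dcfg, hwe=cfg.run_hwe)
            _write_tsv(summary, out / "diversity_summary.tsv",
                       "per-population diversity battery; He = 1 - sum(p^2), "
                       "F = mean (He-Ho)/He over polymorphic loci, FIS = "
                       "Weir-Cockerham ratio-of-sums")
            per_locus = diversity.pooled_locus_summary(gm)
            _write_tsv(per_locus, out / "per_locus.tsv",
                       "pooled per-locus A, Botstein PIC, Ho, He")
            manifest["outputs"] += ["diversity_summary.tsv", "per_locus.tsv"]
            manifest["stages"].append({"stage": stage})

            stage = "differentiation"
            results = differentiation.differentiation_analysis(
                gm, pf, levels=cfg.levels, B=cfg.permutations,
                seed=cfg.stage_seed("differentiation"),
                aggregation=cfg.aggregation, weighted=cfg.weighted,
            )
            bundle = {lvl: r.to_dict() for lvl, r in results.items()}
            (out / "differentiation.json").write_text(
                json.dumps(bundle, indent=1, sort_keys=True)
            )
            if "genepool" in results:
                gene_pool_delta = results["genepool"].delta_j
                snail = differentiation.snail_export(results["genepool"])
                _write_tsv(snail, out / "snail.tsv",
                           f"gene-pool Delta_j and contributions; Delta_SD = "
                           f"{results['genepool'].delta_sd:.6f}")
                manifest["outputs"].append("snail.tsv")
            manifest["outputs"].append("differentiation.json")
            manifest["stages"].append({
                "stage": stage,
                "delta_sd": {lvl: r.delta_sd for lvl, r in results.items()},
            })

            stage = "clustering"
            X = clustering.allele_indicator_matrix(gm)
            cres = clustering.find_clusters(
                X, k_range=cfg.k_range, n_runs=cfg.cluster_runs,
                iters=cfg.kmeans_iters, starts=cfg.kmeans_starts,
                seed=cfg.stage_seed("clustering"),
            )
            klabels = cres.labels[cres.chosen_k]
            n_pca, a_scores = clustering.optimize_a_score(
                X, klabels, seed=cfg.stage_seed("a_score")
            )
            members = clustering.dapc(X, klabels, n_pca)
            table, majority = clustering.population_assignment(members, pf)
            _write_tsv(table, out / "pop_assignment.tsv",
                       f"fraction of individuals per cluster at K={cres.chosen_k}")
            cluster_report = {
                "k_table": json.loads(cres.table.to_json(orient="index")),
                "chosen_k": cres.chosen_k,
                "no_clear_k": cres.no_clear_k,
                "n_pca": n_pca,
                "a_score": {str(k): float(v) for k, v in a_scores.items()},
                "majority_cluster": {p: int(c) for p, c in majority.items()},
            }
            (out / "cluster_report.json").write_text(
                json.dumps(cluster_report, indent=1, sort_keys=True)
            )
            manifest["outputs"] += ["pop_assignment.tsv", "cluster_report.json"]
            manifest["stages"].append({"stage": stage, "chosen_k": cres.chosen_k})

        stage = "mawp"
        if meta is not None and "egu" in meta.columns:
            if gene_pool_delta is None:
                if "delta_j" not in meta.columns:
                    raise ValueError(
                        "MAWP selection needs gene-pool delta_j: run the "
                        "genetics stages or provide a delta_j metadata column"
                    )
                gene_pool_delta = meta["delta_j"]
            decisions = selection.select_mawps(gene_pool_delta, meta, cfg.selection)
            frame = selection.decisions_frame(decisions)
            frame.to_csv(out / "mawp_decisions.csv")
            manifest["outputs"].append("mawp_decisions.csv")
            manifest["stages"].append({
                "stage": stage,
                "selected": int(frame["selected"].sum()),
                "suboptimal": sorted(frame.index[frame["suboptimal"]]),
            })
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
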