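"""One-command orchestration of the full screening workflow.

Reads (or simulates) a two-sowing-date trial, then per trait: combined and
per-condition ANOVA, variance components and broad-sense heritability, and
a condition-means summary with mean reductions. From the yield trait it
builds the ten-index table, HSI classes, the composite mean-rank ordering
and the top-k table, plus trait/index correlation matrices and PCA
coordinates. Every CSV carries a provenance header (version, seed, config
hash) and reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anova import (broad_sense_heritability, combined_anova, lsd,
                    per_condition_anova, variance_components)
from .dataset import (TrialDataset, genotype_condition_means, mean_reduction,
                      read_trial_csv, round_half_away, write_trial_csv)
from .indices import (HsiThresholds, classify_by_hsi, composite_rank,
                      compute_indices, hsi_mp_selection, top_k_table)
from .multivariate import pca, pearson_matrix
from .simulate import SyntheticConfig, generate_trial, paper_scale_config


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    traits: list[str] | None = None
    yield_trait: str = "GY"
    thresholds: HsiThresholds = field(default_factory=HsiThresholds)
    rank_indices: tuple[str, ...] = ("HSI", "MP", "STI")
    alpha: float = 0.05
    outdir: str = "heattrial_out"
    seed: int = 0
    top_k: int = 10

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("specify exactly one of input_path / synthetic")


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: enc(getattr(o, k)) for k in sorted(o.__dataclass_fields__)
                    if k != "outdir"}          # hash the science, not the paths
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in sorted(o.items())}
        return o
    blob = json.dumps(enc(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns a dict of in-memory results.

    Artifacts land in ``cfg.outdir``: the dataset itself (when simulated),
    ANOVA and heritability tables, the index/class/rank tables, the top-k
    table, correlation matrices, PCA coordinates and a run log.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# heattrial v{__version__} seed={cfg.seed} "
              f"config={_config_hash(cfg)}\n")
    log: list[str] = []

    # -- load or simulate --------------------------------------------------
    if cfg.synthetic is not None:
        ds, truth = generate_trial(cfg.synthetic)
        write_trial_csv(ds, out / "trial.csv")
        truth.to_csv(out / "truth.csv", index=False)
        log.append(f"simulated trial: {ds.design}")
    else:
        try:
            ds = read_trial_csv(cfg.input_path)
        except Exception as e:
            raise PipelineError("read", str(e)) from e
        log.append(f"read {cfg.input_path}: {ds.design}")

    traits = cfg.traits or ds.trait_codes()
    design = ds.design
    ny, nr = design["n_years"], design["n_reps"]

    # -- per-trait ANOVA, heritability, condition means --------------------
    results: dict = {"dataset": ds, "anova": {}, "heritability": {}, "means": {}}
    mean_rows = []
    for trait in traits:
        try:
            comb = combined_anova(ds, trait)
        except Exception as e:
            raise PipelineError(f"anova:{trait}", str(e)) from e
        results["anova"][trait] = comb
        _write(comb.formatted(), out / f"anova_combined_{trait}.csv", header)

        row = {"trait": trait}
        for cond, tag in (("normal", "normal"), ("stress", "stress")):
            per = per_condition_anova(ds, trait, cond)
            vc = variance_components(per, ny, nr)
            h2 = broad_sense_heritability(vc, ny, nr, trait, cond)
            results["heritability"][(trait, cond)] = h2
            summ = genotype_condition_means(ds, trait)
            col = "YP" if cond == "normal" else "YS"
            row[f"mean_{tag}"] = summ[col].mean()
            row[f"sd_{tag}"] = summ[col].std(ddof=1)
            row[f"h2b_{tag}"] = (h2.h2b if isinstance(h2.h2b, str)
                                 else round_half_away(100 * h2.h2b, 0))
        row["lsd"] = lsd(comb.ms("Residual"), int(comb.row("Residual")["df"]),
                         design["n_genotypes"] * ny * nr, cfg.alpha)
        row["mean_reduction_pct"] = mean_reduction(row["mean_normal"], row["mean_stress"])
        mean_rows.append(row)
        if summ.attrs["excluded"]:
            log.append(f"{trait}: excluded genotypes {summ.attrs['excluded']}")
    means_tab = pd.DataFrame(mean_rows)
    results["means"] = means_tab
    _write(means_tab, out / "condition_means.csv", header)

    # -- indices on the yield trait ----------------------------------------
    try:
        summ = genotype_condition_means(ds, cfg.yield_trait)
        idx = compute_indices(summ)
        idx = classify_by_hsi(idx, cfg.thresholds)
        ranked = composite_rank(idx, cfg.rank_indices)
    except Exception as e:
        raise PipelineError(f"indices:{cfg.yield_trait}", str(e)) from e
    results["indices"] = ranked
    _write(ranked, out / "index_table.csv", header)
    top = top_k_table(ranked, cfg.top_k)
    results["top_k"] = top
    _write(top, out / "top_genotypes.csv", header)
    sel, line = hsi_mp_selection(idx)
    results["hsi_mp_selected"] = sel
    results["hsi_mp_line"] = line
    _write(sel, out / "hsi_mp_selection.csv", header)

    # -- correlations and PCA ----------------------------------------------
    index_corr = pearson_matrix(
        ranked, ["YP", "YS", "TOL", "MP", "GMP", "HM", "HSI", "YSI",
                 "STI", "YI", "MRP", "PYR"])
    results["index_correlation"] = index_corr
    _write(index_corr.r.reset_index(names="index"),
           out / "index_correlations.csv", header)

    for cond, col in (("normal", "YP"), ("stress", "YS")):
        wide = pd.DataFrame({
            t: genotype_condition_means(ds, t).set_index("genotype")[col]
            for t in traits})
        corr = pearson_matrix(wide)
        results[f"trait_correlation_{cond}"] = corr
        _write(corr.r.reset_index(names="trait"),
               out / f"trait_correlations_{cond}.csv", header)
        if len(wide.columns) >= 2:
            res = pca(wide)
            results[f"pca_{cond}"] = res
            _write(res.scores.reset_index(names="genotype"),
                   out / f"pca_scores_{cond}.csv", header)
            _write(res.loadings.reset_index(names="trait"),
                   out / f"pca_loadings_{cond}.csv", header)

    (out / "run.log").write_text(header + "\n".join(log) + "\n")
    return results


def default_synthetic_run(seed: int = 0, outdir: str = "heattrial_out",
                          n_genotypes: int = 156) -> RunConfig:
    return RunConfig(synthetic=paper_scale_config(seed=seed, n_genotypes=n_genotypes),
                     outdir=outdir, seed=seed)
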