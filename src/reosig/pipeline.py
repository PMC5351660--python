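"""End-to-end orchestration of the synthetic REO study.

``run_all`` executes the full sequence — simulate a paired FF/FFPE normal
cohort, score FF-vs-FFPE REO consistency at several exclusion fractions,
mine highly stable pairs and check their maintenance in FFPE samples,
train a reversal-pair signature on a two-phenotype cohort, validate it on
freshly generated FF and FFPE test cohorts, and run the Rank Product
differential-expression stage — writing TSV artifacts plus one
machine-readable JSON summary.  Outputs are byte-reproducible from the
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import rankprod, ranking, stable
from .classify import evaluate
from .io import write_matrix, write_pairing
from .signature import ReversalPairSignatureModel
from .simulate import GeneratorConfig, degrade_to_ffpe, make_ff_cohort, make_two_class_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Defaults are the study thresholds: stable-pair support 0.99, reversal
    consistency 0.85 (strict), exclusion fractions {0, 0.1, 0.2} and a
    five-pair signature.
    """

    outdir: str = "reosig_run"
    seed: int = 0
    n_genes: int = 2000
    n_train_samples: int = 80
    n_test_samples: int = 100
    n_normal_samples: int = 60
    n_paired_samples: int = 12
    stable_threshold: float = 0.99
    reversal_threshold: float = 0.85
    fractions: tuple[float, ...] = (0.0, 0.1, 0.2)
    k: int = 5
    rp_n_perm: int = 200
    rp_fdr: float = 0.05
    sample_sd: float = 0.4
    deg_shift_sd: float = 0.45
    deg_noise_sd: float = 0.3
    reversal_delta: float = 1.5
    class0_name: str = "cirrhosis"
    class1_name: str = "hcc"

    def generator(self, **kw) -> GeneratorConfig:
        base = dict(
            n_genes=self.n_genes,
            seed=self.seed,
            sample_sd=self.sample_sd,
            deg_shift_sd=self.deg_shift_sd,
            deg_noise_sd=self.deg_noise_sd,
            reversal_delta=self.reversal_delta,
        )
        base.update(kw)
        return GeneratorConfig(**base)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def _round(x: float) -> float:
    return float(round(float(x), 10))


def run_all(cfg: RunConfig) -> dict:
    """Run every stage on synthetic data; returns (and writes) the summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": dataclasses.asdict(cfg)}
    log_lines: list[str] = [f"run_all seed={cfg.seed} n_genes={cfg.n_genes}"]

    def _log(msg: str) -> None:
        log_lines.append(msg)
        logger.info(msg)

    # --- paired normal cohort: consistency + rank product -----------------
    paired_gen = cfg.generator(n_samples=cfg.n_paired_samples)
    ff_paired = make_ff_cohort(paired_gen)
    cohort = degrade_to_ffpe(ff_paired, paired_gen)
    write_matrix(cohort.ff, out / "paired_ff.tsv")
    write_matrix(cohort.ffpe, out / "paired_ffpe.tsv")
    write_pairing(cohort.pairing, out / "pairing.tsv")

    _log(f"simulated paired cohort: {cfg.n_paired_samples} FF/FFPE pairs")
    report = ranking.cohort_consistency(cohort, cfg.fractions)
    report.to_tsv(out / "consistency.tsv")
    _log(f"consistency means: {report.mean_scores()}")
    summary["consistency_mean_by_fraction"] = {
        f"{f:g}": _round(s) for f, s in report.mean_scores().items()
    }

    rp = rankprod.rank_product_test(
        cohort, n_perm=cfg.rp_n_perm, seed=cfg.seed
    )
    rp.to_csv(out / "rankprod.tsv", sep="\t", float_format="%.10g",
              lineterminator="\n")
    deg_mask = (rp["fdr_up"] < cfg.rp_fdr) | (rp["fdr_down"] < cfg.rp_fdr)
    deg_ids = rp.index[deg_mask]
    fc = rankprod.paired_fold_changes(cohort)
    bins = rankprod.fold_change_bins(fc, deg_ids)
    summary["rankprod"] = {
        "n_deg": int(deg_mask.sum()),
        "n_deg_2fold": int(bins[["[1,2)", "[2,3)", ">=3"]].sum()),
        "fold_change_bins": {k: int(v) for k, v in bins.items()},
    }

    # --- second "tissue" on the same gene universe: degradation shifts are
    # gene-specific, so DEG directions should agree across tissues --------
    gen2 = paired_gen.replace(noise_seed=cfg.seed + 3)
    cohort2 = degrade_to_ffpe(make_ff_cohort(gen2, sample_prefix="T2S"), gen2)
    rp2 = rankprod.rank_product_test(cohort2, n_perm=cfg.rp_n_perm,
                                     seed=cfg.seed + 3)
    deg2_mask = (rp2["fdr_up"] < cfg.rp_fdr) | (rp2["fdr_down"] < cfg.rp_fdr)
    maps = {
        "tissue1": np.sign(rp.loc[deg_mask, "mean_log2fc"]),
        "tissue2": np.sign(rp2.loc[deg2_mask, "mean_log2fc"]),
    }
    overlap = set(maps["tissue1"].index) & set(maps["tissue2"].index)
    if overlap:
        dc = rankprod.direction_consistency_test(maps)
        summary["direction_consistency"] = {
            "n_overlap": dc.n_overlap,
            "consistent_fraction": _round(dc.consistent_fraction),
            "p_value": _round(dc.p_value),
        }
    else:
        summary["direction_consistency"] = {
            "n_overlap": 0, "consistent_fraction": None, "p_value": None,
        }

    # --- stable-pair mining on an accumulated normal cohort ---------------
    normal_gen = cfg.generator(n_samples=cfg.n_normal_samples)
    normal_ff = make_ff_cohort(normal_gen, sample_prefix="N")
    stable_set = stable.mine_stable_pairs(normal_ff, cfg.stable_threshold)
    stable_set.to_tsv(out / "stable_pairs.tsv")
    normal_cohort = degrade_to_ffpe(normal_ff, normal_gen)
    maintained = [
        stable.maintained_fraction(stable_set, normal_cohort.ffpe.sample(s))[0]
        for s in normal_cohort.ffpe.sample_ids
    ]
    _log(f"stable pairs at {cfg.stable_threshold}: {len(stable_set)}")
    summary["stable_pairs"] = {
        "n_stable": len(stable_set),
        "threshold": cfg.stable_threshold,
        "maintained_fraction_mean": _round(float(np.mean(maintained))),
        "maintained_fraction_min": _round(float(np.min(maintained))),
    }

    # --- signature training ------------------------------------------------
    train_gen = cfg.generator(n_samples=cfg.n_train_samples)
    train = make_two_class_cohort(train_gen)
    model = ReversalPairSignatureModel(
        train.class0, train.class1, threshold=cfg.reversal_threshold,
        class0_name=cfg.class0_name, class1_name=cfg.class1_name,
    )
    results = model.fit(k=cfg.k)
    results.signature.to_tsv(out / "signature.tsv")
    (out / "summary.txt").write_text(results.summary() + "\n")
    implanted = {tuple(p[:2]) for p in train.implanted}
    selected = {(p.gene_a, p.gene_b) for p in results.signature.pairs}
    summary["signature"] = {
        "k": results.signature.k,
        "n_candidates": results.n_candidates,
        "n_implanted_recovered": len(implanted & selected),
        "n_implanted": len(implanted),
        "training_sensitivity": {
            name: _round(v)
            for name, v in results.training_sensitivities().items()
        },
    }

    # --- validation on fresh test cohorts (FF and FFPE-degraded) ----------
    test_gen = train_gen.replace(
        n_samples=cfg.n_test_samples, noise_seed=cfg.seed + 1
    )
    test = make_two_class_cohort(test_gen)
    val: dict[str, dict[str, float]] = {}
    preds = []
    for storage, m0, m1 in (
        ("FF", test.class0, test.class1),
        (
            "FFPE",
            degrade_to_ffpe(test.class0, test_gen).ffpe,
            degrade_to_ffpe(
                test.class1, test_gen.replace(noise_seed=cfg.seed + 2)
            ).ffpe,
        ),
    ):
        sens0, frame0 = evaluate(results.signature, m0, cfg.class0_name)
        sens1, frame1 = evaluate(results.signature, m1, cfg.class1_name)
        val[storage] = {
            cfg.class0_name: _round(sens0),
            cfg.class1_name: _round(sens1),
        }
        for frame, label in ((frame0, cfg.class0_name), (frame1, cfg.class1_name)):
            frame = frame.assign(storage=storage, true_label=label)
            preds.append(frame)
    summary["validation_sensitivity"] = val
    pd.concat(preds, ignore_index=True).to_csv(
        out / "predictions.tsv", sep="\t", index=False, lineterminator="\n"
    )

    _log(f"signature: {[p.class0_direction for p in results.signature.pairs]}")
    _log(f"validation sensitivity: {val}")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log("pipeline complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
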