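"""End-to-end orchestration: simulate -> preprocess -> features -> evaluate.

``run_pipeline`` executes the full analysis described by a
:class:`~nirspace.config.RunConfig` and, optionally, writes a results
bundle: per-fold loss tables (CSV), the accuracy-vs-learner-count curve
(CSV), a JSON summary, and a structured log with every seed so any fold can
be replayed.  The run is deterministic given the config: the same config
produces a byte-identical summary JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import ChromophoreEpochs
from .ensemble import subset_size_ladder
from .evaluate import (
    compare_over_learner_counts,
    ladder_search,
    repeated_kfold,
    strong_factory,
)
from .features import FeatureMatrix, build_feature_matrix
from .preprocess import preprocess_session
from .synthdata import SessionParams, simulate_session

__all__ = ["run_pipeline", "simulate_epochs", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def simulate_epochs(config: RunConfig) -> ChromophoreEpochs:
    """Simulate one session per the config and preprocess it to epochs."""
    syn = config.synthdata
    params = SessionParams(
        n_channels=syn.n_channels,
        n_trials_per_class=syn.n_trials_per_class,
        hrf_amplitude_hbo=syn.hrf_amplitude_hbo,
        hrf_amplitude_hbr=syn.hrf_amplitude_hbr,
        responsive_channel_fraction=syn.responsive_channel_fraction,
        seed=config.stage_seed("synthdata"),
    )
    od, events = simulate_session(params)
    return preprocess_session(
        od,
        events,
        low=config.filter.low,
        high=config.filter.high,
        order=config.filter.order,
        window=config.epoch.window,
        ref=config.epoch.baseline,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; return (and optionally write) the results bundle.

    The bundle holds the feature dimensionality, the subset-size ladder with
    per-M cross-validated accuracies (when ``ensemble.M == "auto"``), the
    strong-learner accuracies on the same fold partitions, the
    accuracy-vs-learner-count curve with FDR-adjusted significance, and the
    corrected t-test of the final ensemble against the strong learner.
    """
    epochs = _stage("simulate+preprocess")(simulate_epochs, config)

    feat_cfg = config.features
    fm: FeatureMatrix = _stage("features")(
        build_feature_matrix,
        epochs,
        features=feat_cfg.features,
        scheme=feat_cfg.window_type,
        slope_method=feat_cfg.slope_method,
    )

    ev = config.evaluate
    cv_seed = config.stage_seed("cv")
    ens_cfg = config.ensemble

    ladder_acc: dict[int, float] = {}
    if ens_cfg.M == "auto":
        best_m, per_m = _stage("ladder-search")(
            ladder_search, fm, N=ens_cfg.N, R=ev.R, K=ev.K, seed=cv_seed
        )
        ladder_acc = {m: res.mean_accuracy for m, res in per_m.items()}
        M = best_m
    else:
        M = int(ens_cfg.M)

    n_grid = tuple(n for n in ev.n_grid if n <= ens_cfg.N)
    comparison = _stage("compare")(
        compare_over_learner_counts,
        fm,
        M=M,
        N=ens_cfg.N,
        strong_kind=ens_cfg.strong_kind,
        n_grid=n_grid,
        R=ev.R,
        K=ev.K,
        seed=cv_seed,
        df=ev.df,
        test=ev.test,
    )
    strong_lda = _stage("strong-lda")(
        repeated_kfold, fm, strong_factory("lda"), R=ev.R, K=ev.K, seed=cv_seed
    )

    final = comparison.tests[-1]
    results = {
        "config": config.to_dict(),
        "n_trials": int(fm.n_trials),
        "feature_dimension": int(fm.n_features),
        "subset_ladder": [int(m) for m in subset_size_ladder(fm.n_features)],
        "ladder_accuracy": {str(m): round(a, 10) for m, a in sorted(ladder_acc.items())},
        "chosen_M": int(M),
        "ensemble_accuracy": round(float(comparison.ensemble_accuracy[-1]), 10),
        "strong_accuracy": {
            config.ensemble.strong_kind: round(comparison.strong_accuracy, 10),
            "lda": round(strong_lda.mean_accuracy, 10),
        },
        "learner_count_curve": {
            "n": [int(n) for n in comparison.n_grid],
            "accuracy": [round(float(a), 10) for a in comparison.ensemble_accuracy],
            "p_fdr": [round(float(p), 10) for p in comparison.p_fdr],
            "significant": [bool(s) for s in comparison.significant],
        },
        "corrected_t_test": {
            "mean_diff": round(final.mean_diff, 10),
            "overall_var": round(final.overall_var, 10),
            "t": round(final.t, 10),
            "df": final.df,
            "p": round(final.p, 10),
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(results, indent=1, sort_keys=True) + "\n"
        )
        _losses_frame(comparison.strong_losses).to_csv(
            out / f"losses_{config.ensemble.strong_kind}.csv", index=False
        )
        _losses_frame(comparison.ensemble_losses[:, :, -1]).to_csv(
            out / "losses_ensemble.csv", index=False
        )
        curve = pd.DataFrame(results["learner_count_curve"])
        curve.to_csv(out / "accuracy_vs_n.csv", index=False)
        log_lines = [
            f"master_seed={config.seed}",
            f"cv_seed={cv_seed}",
            f"synthdata_seed={config.stage_seed('synthdata')}",
            f"chosen_M={M}",
        ]
        for r in range(ev.R):
            for k in range(ev.K):
                log_lines.append(
                    f"fold r={r} k={k} ensemble_loss="
                    f"{comparison.ensemble_losses[r, k, -1]:.6f} "
                    f"strong_loss={comparison.strong_losses[r, k]:.6f}"
                )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _losses_frame(losses: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(
        losses, columns=[f"fold{k}" for k in range(losses.shape[1])]
    )
    df.insert(0, "repetition", np.arange(losses.shape[0]))
    return df
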