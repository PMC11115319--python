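"""Hyperparameter selection and model-comparison statistics.

Models are fitted over a grid of input scale x core layer x L1 penalty x
seed; test scores are only ever reported for the configuration that
maximizes validation score (seeds averaged).  Population comparisons use:

* pairwise Wilcoxon signed-rank tests on per-neuron score differences
  between task clusters, Holm-Bonferroni corrected over the pairs;
* a specialization index: the variance across task models of normalized
  performance — by default the increment over the untrained baseline divided
  by its mean across tasks (the baseline itself excluded) — compared between
  areas with both Bartlett's test (optionally after Fisher z-transforming
  correlation scores) and Levene's test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: per-layer L1 grids used for model selection
LAMBDA_GRIDS = {
    "conv1": (0.33, 1.0, 3.0),
    "layer1.0": (3.0,),
    "layer2.0": (3.0, 6.0),
    "layer3.0": (3.0, 9.0),
    "layer4.0": (6.0, 12.0),
}

#: canonical layer ordering used for tie-breaking
LAYER_ORDER = tuple(LAMBDA_GRIDS)


@dataclass(frozen=True)
class ModelConfig:
    area: str
    core_id: str
    layer_id: str
    scale: float           # input resolution, px/deg
    l1: float
    seed: int | None = None


def _layer_rank(layer_id: str) -> int:
    try:
        return LAYER_ORDER.index(layer_id)
    except ValueError:
        return len(LAYER_ORDER)


def grid_select(table: pd.DataFrame, area: str = "") -> dict[str, ModelConfig]:
    """Best configuration per core by validation score.

    ``table`` needs columns ``core_id, layer_id, scale, l1, seed, val_score``.
    Seeds are averaged before the argmax; ties break toward the smallest L1,
    then the earliest layer.  Row order never affects the result.
    """
    if len(table) == 0:
        raise ValueError("empty results table")
    required = {"core_id", "layer_id", "scale", "l1", "val_score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    pooled = (table.groupby(["core_id", "layer_id", "scale", "l1"], as_index=False)
              ["val_score"].mean())
    pooled["layer_rank"] = pooled["layer_id"].map(_layer_rank)
    best: dict[str, ModelConfig] = {}
    for core_id, group in pooled.groupby("core_id"):
        group = group.sort_values(
            ["val_score", "l1", "layer_rank"],
            ascending=[False, True, True], kind="mergesort",
        )
        row = group.iloc[0]
        best[core_id] = ModelConfig(area=area, core_id=core_id,
                                    layer_id=row["layer_id"],
                                    scale=float(row["scale"]), l1=float(row["l1"]))
    return best


def cluster_contrasts(scores_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise signed-rank tests between task clusters on paired neurons.

    Each group's array holds one score per neuron, aligned across groups
    (the same neurons in the same order — a paired design).  Returns one row
    per pair with the Wilcoxon statistic, raw p, and Holm-adjusted p.
    """
    groups = list(scores_by_group)
    lengths = {len(np.asarray(v)) for v in scores_by_group.values()}
    if len(lengths) != 1:
        raise ValueError("paired design requires equal neuron counts per group")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        diff = np.asarray(scores_by_group[a], float) - np.asarray(scores_by_group[b], float)
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(diff)
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_raw": p})
    out = pd.DataFrame(rows)
    _, p_holm, _, _ = multipletests(out["p_raw"], method="holm")
    out["p_holm"] = p_holm
    return out


def normalized_performance(scores: np.ndarray, baseline: float,
                           convention: str = "baseline_increment",
                           fisher_z: bool = False) -> np.ndarray:
    """Per-core normalized performance used by the specialization index.

    ``baseline_increment``: (score - baseline) / mean(score - baseline);
    ``mean_normalized``: score / mean(score).  The untrained baseline itself
    is never part of the returned set.  With ``fisher_z`` the scores and
    baseline (assumed correlations) are arctanh-transformed first.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 cores besides the baseline")
    if fisher_z:
        scores = np.arctanh(scores)
        baseline = float(np.arctanh(baseline))
    if convention == "baseline_increment":
        inc = scores - baseline
        return inc / inc.mean()
    if convention == "mean_normalized":
        return scores / scores.mean()
    raise ValueError(f"unknown convention {convention!r}")


def specialization_index(scores: np.ndarray, baseline: float,
                         convention: str = "baseline_increment",
                         fisher_z: bool = False) -> float:
    """Variance of normalized performance across task models (ddof=1)."""
    return float(np.var(normalized_performance(scores, baseline, convention,
                                               fisher_z), ddof=1))


def specialization_test(scores_a: np.ndarray, baseline_a: float,
                        scores_b: np.ndarray, baseline_b: float,
                        convention: str = "baseline_increment",
                        fisher_z: bool = True) -> dict:
    """Compare specialization between two areas.

    Both Bartlett's and Levene's tests for equality of variances are
    reported on the two areas' normalized-performance sets (neither is
    privileged); the indices themselves are included for reference.
    """
    na = normalized_performance(scores_a, baseline_a, convention, fisher_z)
    nb = normalized_performance(scores_b, baseline_b, convention, fisher_z)
    bart = sps.bartlett(na, nb)
    lev = sps.levene(na, nb)
    return {
        "index_a": float(np.var(na, ddof=1)),
        "index_b": float(np.var(nb, ddof=1)),
        "bartlett_stat": float(bart.statistic), "bartlett_p": float(bart.pvalue),
        "levene_stat": float(lev.statistic), "levene_p": float(lev.pvalue),
        "n": int(na.size),
    }
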