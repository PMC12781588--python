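"""The probe-selection funnel that defines an episignature.

Stages, in order: (1) exclude probes with mean methylation difference
below the effect floor (|delta beta| >= 0.05 retained — the boundary is
inclusive); (2) rank the remainder by a composite score
``|delta beta| * (-log10 p_adj)`` and keep the top N (default 1000);
(3) retain probes with fold-direction-invariant ROC AUC at or above the
threshold; (4) greedily prune probes highly Pearson-correlated with a
higher-ranked kept probe.  The surviving ordered probe set, its
statistics, the parameters and the training-group reference means form
the :class:`Episignature`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import SelectionError
from .io_qc import BetaMatrix

P_ADJ_FLOOR = 1e-300  # floor before -log10 so p_adj = 0 stays finite


@dataclass
class SelectionParams:
    min_abs_delta: float = 0.05
    top_n: int = 1000
    auc_min: float = 0.85
    corr_max: float = 0.85
    final_range: tuple[int, int] = (160, 500)

    def __post_init__(self) -> None:
        if not (0.0 < self.min_abs_delta < 1.0):
            raise SelectionError("min_abs_delta must be in (0, 1)")
        if not (0.5 <= self.auc_min <= 1.0):
            raise SelectionError("auc_min must be in [0.5, 1]")
        if not (0.0 < self.corr_max < 1.0):
            raise SelectionError("corr_max must be in (0, 1)")


@dataclass
class Episignature:
    """A selected, ordered probe set with its provenance."""

    probe_ids: list[str]
    stats: pd.DataFrame  # per selected probe: delta_beta, t, p, auc, composite
    params: SelectionParams
    training_sample_ids: list[str]
    reference_means: pd.DataFrame  # per probe: case_mean, control_mean
    stage_counts: dict[str, int]
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise SelectionError("episignature probe ids must be unique")

    def to_json(self, path: str | Path, include_timestamp: bool = False) -> None:
        """Serialize; the creation timestamp is omitted by default so that
        re-runs with identical inputs produce byte-identical artifacts."""
        payload = {
            "probe_ids": self.probe_ids,
            "stats": self.stats.reset_index().to_dict(orient="list"),
            "params": {**asdict(self.params), "final_range": list(self.params.final_range)},
            "training_sample_ids": self.training_sample_ids,
            "reference_means": self.reference_means.reset_index().to_dict(orient="list"),
            "stage_counts": self.stage_counts,
        }
        if include_timestamp:
            payload["created"] = self.created
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Episignature":
        payload = json.loads(Path(path).read_text())
        params = payload["params"]
        params["final_range"] = tuple(params["final_range"])
        return cls(
            probe_ids=payload["probe_ids"],
            stats=pd.DataFrame(payload["stats"]).set_index("probe_id"),
            params=SelectionParams(**params),
            training_sample_ids=payload["training_sample_ids"],
            reference_means=pd.DataFrame(payload["reference_means"]).set_index("probe_id"),
            stage_counts=payload["stage_counts"],
            created=payload.get("created", ""),
        )


def composite_score(delta_beta: np.ndarray, p_adj: np.ndarray) -> np.ndarray:
    """Effect-size x confidence score: |delta beta| * (-log10 p_adj)."""
    p = np.maximum(np.asarray(p_adj, dtype=float), P_ADJ_FLOOR)
    return np.abs(delta_beta) * (-np.log10(p))


def composite_rank(stats: pd.DataFrame) -> pd.DataFrame:
    """Order probes by descending composite score.

    Ties break by larger |delta beta|, then lexicographic probe id, so
    the ranking is invariant to input order.
    """
    df = stats.copy()
    df["composite"] = composite_score(df["delta_beta"].to_numpy(), df["p_adj"].to_numpy())
    df["_absdb"] = df["delta_beta"].abs()
    df = df.sort_values(
        by=["composite", "_absdb", "probe_id"]
        if "probe_id" in df.columns
        else ["composite", "_absdb"],
        ascending=[False, False, True] if "probe_id" in df.columns else [False, False],
        kind="mergesort",
    )
    if "probe_id" not in df.columns:
        df = df.iloc[np.lexsort((df.index, -df["_absdb"], -df["composite"]))]
    return df.drop(columns="_absdb")


def filter_by_effect(stats: pd.DataFrame, min_abs_delta: float = 0.05) -> pd.DataFrame:
    """Retain probes with |delta beta| >= ``min_abs_delta`` (boundary kept)."""
    out = stats[stats["delta_beta"].abs() >= min_abs_delta]
    if out.empty:
        raise SelectionError(
            "no probes survive the effect-size filter; review min_abs_delta"
        )
    return out


def probe_auc(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Direction-folded ROC AUC for one probe.

    Computed as the Mann-Whitney U statistic over case/control pairs
    (ties count 0.5), normalised by ``n_case * n_control``, and folded to
    ``max(AUC, 1 - AUC)`` so hypo- and hypermethylated probes score alike.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise SelectionError("both groups must be non-empty for AUC")
    combined = np.concatenate([case_values, control_values])
    ranks = _sps.rankdata(combined)
    n1 = case_values.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * control_values.size)
    return float(max(auc, 1.0 - auc))


def _auc_vectorized(case_mat: np.ndarray, ctrl_mat: np.ndarray) -> np.ndarray:
    """Folded AUC per probe (rows) for case/control sample columns."""
    n1, n0 = case_mat.shape[1], ctrl_mat.shape[1]
    both = np.concatenate([case_mat, ctrl_mat], axis=1)
    ranks = _sps.rankdata(both, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return np.maximum(auc, 1.0 - auc)


def correlation_prune(
    beta: BetaMatrix, ranked_ids: list[str], corr_max: float = 0.85
) -> list[str]:
    """Greedy scan in rank order: keep a probe iff its |Pearson r| with
    every already-kept probe is <= ``corr_max``.

    Zero-variance probes correlate as 0 (with a warning) and are kept.
    Correlations are computed across the supplied (training) samples only.
    """
    missing = set(ranked_ids) - set(beta.probe_ids)
    if missing:
        raise SelectionError(f"ranked probes absent from beta: {sorted(missing)[:5]}")
    if not ranked_ids:
        return []
    mat = beta.values.loc[ranked_ids].to_numpy(dtype=float)
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance probe(s) during pruning; correlation treated as 0")
    centered = mat - mat.mean(axis=1, keepdims=True)
    denom = np.where(sd == 0, 1.0, sd * np.sqrt(mat.shape[1]))
    normed = centered / denom[:, None]
    normed[sd == 0] = 0.0
    corr = np.abs(normed @ normed.T)
    kept_idx: list[int] = []
    for i in range(len(ranked_ids)):
        if all(corr[i, j] <= corr_max for j in kept_idx):
            kept_idx.append(i)
    return [ranked_ids[i] for i in kept_idx]


def select_probes(
    stats: pd.DataFrame,
    beta: BetaMatrix,
    case_ids: list[str],
    control_ids: list[str],
    params: SelectionParams | None = None,
) -> Episignature:
    """Run the full funnel and assemble the episignature.

    ``stats`` must carry ``delta_beta``, ``p_adj`` indexed by probe id;
    ``beta`` must contain the training samples.  A warning (not an error)
    fires when the final probe count falls outside ``params.final_range``.
    """
    params = params or SelectionParams()
    training = list(case_ids) + list(control_ids)
    train_beta = beta.subset_samples(training)

    counts = {"input": len(stats)}
    by_effect = filter_by_effect(stats.copy(), params.min_abs_delta)
    counts["effect_filter"] = len(by_effect)

    ranked = composite_rank(by_effect.reset_index())
    top = ranked.head(params.top_n)
    counts["top_n"] = len(top)

    top_ids = list(top["probe_id"])
    sub = train_beta.subset_probes(top_ids)
    case_mat = sub.values[list(case_ids)].to_numpy(dtype=float)
    ctrl_mat = sub.values[list(control_ids)].to_numpy(dtype=float)
    aucs = _auc_vectorized(case_mat, ctrl_mat)
    auc_by_probe = pd.Series(aucs, index=top_ids)
    keep_auc = [pid for pid, a in auc_by_probe.items() if a >= params.auc_min]
    counts["auc_filter"] = len(keep_auc)
    if not keep_auc:
        raise SelectionError("no probes reach the AUC threshold")

    final_ids = correlation_prune(train_beta, keep_auc, params.corr_max)
    counts["correlation_prune"] = len(final_ids)

    lo, hi = params.final_range
    if not (lo <= len(final_ids) <= hi):
        warnings.warn(
            f"final probe count {len(final_ids)} outside the expected "
            f"range [{lo}, {hi}]"
        )

    sel_stats = ranked.set_index("probe_id").loc[final_ids]
    sel_stats["auc"] = auc_by_probe.loc[final_ids]
    fsub = train_beta.subset_probes(final_ids)
    ref = pd.DataFrame(
        {
            "case_mean": fsub.values[list(case_ids)].mean(axis=1),
            "control_mean": fsub.values[list(control_ids)].mean(axis=1),
        }
    )
    ref.index.name = "probe_id"
    return Episignature(
        probe_ids=final_ids,
        stats=sel_stats,
        params=params,
        training_sample_ids=training,
        reference_means=ref,
        stage_counts=counts,
    )
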