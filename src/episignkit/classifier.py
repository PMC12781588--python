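"""SVM-based episignature classification and validation diagnostics.

The methylation-variant-pathogenicity (MVP) score of a sample is the
calibrated probability that it matches an episignature.  Four linear
support-vector machines are trained, each on the cases, their matched
controls, and three quarters of a reference database of other-disorder
and unaffected samples; the held-out quarter rotates so every database
sample is scored by a model that never saw it.  External/query samples
receive the mean probability over all four fold models — the "average
SVM" that defines the MVP score.  Diagnostics include leave-one-out
cross-validation of the entire selection + training procedure, classical
(Torgerson) multidimensional scaling, and Ward hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .diffmeth import differential_analysis
from .errors import AlignmentError, TrainingError, EpisignError
from .io_qc import BetaMatrix, SampleSheet
from .selection import Episignature, SelectionParams, select_probes

N_FOLDS = 4
CALL_POSITIVE = 0.5
CALL_NEGATIVE = 0.1


@dataclass
class TrainingPool:
    """Ids of the training cases, matched controls, and database samples."""

    case_ids: list[str]
    matched_control_ids: list[str]
    database_ids: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.case_ids), set(self.matched_control_ids), set(self.database_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise TrainingError("training pool id sets must be disjoint")


@dataclass
class _Fold:
    svm: SVC
    platt: LogisticRegression


@dataclass
class MVPModel:
    """Four fold-wise linear SVMs with Platt-style probability calibration."""

    episignature: Episignature
    folds: list[_Fold]
    fold_membership: dict[str, int]  # database id -> held-out fold
    seed: int
    cost: float = 1.0

    def probe_ids(self) -> list[str]:
        return self.episignature.probe_ids


def _features(beta: BetaMatrix, probe_ids: list[str], sample_ids: list[str],
              reference_means: pd.DataFrame | None = None) -> np.ndarray:
    """Samples x probes feature block; missing probes are imputed from the
    training reference means (error above 5% missing)."""
    present = [p for p in probe_ids if p in set(beta.probe_ids)]
    n_missing = len(probe_ids) - len(present)
    if n_missing:
        if reference_means is None or n_missing / len(probe_ids) > 0.05:
            raise AlignmentError(
                f"{n_missing}/{len(probe_ids)} signature probes missing from beta"
            )
        warnings.warn(f"imputing {n_missing} missing signature probes from reference means")
    sub = beta.subset_samples(sample_ids)
    block = np.empty((len(sample_ids), len(probe_ids)))
    present_set = set(present)
    vals = sub.values
    for j, pid in enumerate(probe_ids):
        if pid in present_set:
            block[:, j] = vals.loc[pid].to_numpy(dtype=float)
        else:
            ref = reference_means.loc[pid]
            block[:, j] = 0.5 * (ref["case_mean"] + ref["control_mean"])
    return block


def _fit_platt(margins: np.ndarray, labels: np.ndarray) -> LogisticRegression:
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(margins.reshape(-1, 1), labels)
    return lr


def train_mvp(
    episig: Episignature,
    beta: BetaMatrix,
    pool: TrainingPool,
    seed: int = 0,
    cost: float = 1.0,
) -> MVPModel:
    """Train the four-fold MVP classifier.

    Database ids are partitioned into four seeded folds; fold k's SVM is
    trained on cases + matched controls + the other three database folds,
    labelling cases 1 against everything else, with class weights
    inversely proportional to class size.  Margins are calibrated to
    probabilities by a logistic fit on the training margins.
    """
    if len(pool.database_ids) < N_FOLDS:
        raise TrainingError(f"need at least {N_FOLDS} database samples")
    all_ids = pool.case_ids + pool.matched_control_ids + pool.database_ids
    missing = set(all_ids) - set(beta.sample_ids)
    if missing:
        raise AlignmentError(f"pool ids absent from beta: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool.database_ids))
    fold_membership = {
        pool.database_ids[i]: int(k % N_FOLDS) for k, i in enumerate(order)
    }

    probes = episig.probe_ids
    ref = episig.reference_means
    folds: list[_Fold] = []
    for k in range(N_FOLDS):
        db_in = [s for s in pool.database_ids if fold_membership[s] != k]
        train_ids = pool.case_ids + pool.matched_control_ids + db_in
        X = _features(beta, probes, train_ids, ref)
        y = np.array([1] * len(pool.case_ids) + [0] * (len(train_ids) - len(pool.case_ids)))
        svm = SVC(kernel="linear", C=cost, class_weight="balanced")
        svm.fit(X, y)
        platt = _fit_platt(svm.decision_function(X), y)
        folds.append(_Fold(svm=svm, platt=platt))
    return MVPModel(
        episignature=episig, folds=folds, fold_membership=fold_membership,
        seed=seed, cost=cost,
    )


def score_samples(
    model: MVPModel,
    beta: BetaMatrix,
    sample_ids: list[str],
    positive_threshold: float = CALL_POSITIVE,
    negative_threshold: float = CALL_NEGATIVE,
) -> pd.DataFrame:
    """MVP scores and calls for the given samples.

    Database members are scored only by their held-out fold model; any
    other sample gets the mean calibrated probability over all four
    folds.  Calls: positive >= ``positive_threshold``, negative <=
    ``negative_threshold``, else inconclusive.
    """
    unknown = set(sample_ids) - set(beta.sample_ids)
    if unknown:
        raise AlignmentError(f"unknown sample ids: {sorted(unknown)[:5]}")
    X = _features(beta, model.probe_ids(), list(sample_ids), model.episignature.reference_means)
    per_fold = np.column_stack(
        [f.platt.predict_proba(f.svm.decision_function(X).reshape(-1, 1))[:, 1]
         for f in model.folds]
    )
    rows = []
    for i, sid in enumerate(sample_ids):
        held = model.fold_membership.get(sid)
        if held is None:
            score = float(per_fold[i].mean())
            detail = per_fold[i].tolist()
        else:
            score = float(per_fold[i, held])
            detail = [float(per_fold[i, held])]
        call = (
            "positive" if score >= positive_threshold
            else "negative" if score <= negative_threshold
            else "inconclusive"
        )
        rows.append(
            {
                "sample_id": sid,
                "score": score,
                "call": call,
                "held_out_fold": -1 if held is None else held,
                "per_fold_scores": detail,
            }
        )
    return pd.DataFrame(rows)


def loocv_discovery(
    beta: BetaMatrix,
    sheet: SampleSheet,
    pool: TrainingPool,
    params: SelectionParams | None = None,
    seed: int = 0,
    adjust_cells: bool = True,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of the whole discovery procedure.

    For each case: drop it, redo the differential analysis and probe
    selection on the remaining cases vs controls, retrain the MVP model,
    and score the held-out case with the fold-averaged probability.
    Returns one row per case with its held-out score and the Jaccard
    overlap between the fold's probe set and the all-case probe set.
    When a fold's selection funnel finds no probes (no detectable
    signature without that case), the held-out score is recorded as 0.0
    with ``fold_failed`` set — absence of a signature is a negative call.
    """
    if len(pool.case_ids) < 4:
        raise TrainingError("leave-one-out needs at least 4 cases")
    params = params or SelectionParams()

    def _discover(case_ids: list[str]) -> Episignature:
        keep = case_ids + pool.matched_control_ids
        sub_sheet = sheet.subset(keep)
        stats = differential_analysis(
            beta.subset_samples(keep), sub_sheet, adjust_cells=adjust_cells
        )
        return select_probes(stats, beta, case_ids, pool.matched_control_ids, params)

    from .errors import SelectionError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full_set = set(_discover(pool.case_ids).probe_ids)
        except SelectionError:
            full_set = set()

    rows = []
    for held in pool.case_ids:
        rest = [c for c in pool.case_ids if c != held]
        failed = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                episig = _discover(rest)
                sub_pool = TrainingPool(rest, pool.matched_control_ids, pool.database_ids)
                model = train_mvp(episig, beta, sub_pool, seed=seed)
                score = float(score_samples(model, beta, [held])["score"].iloc[0])
                s = set(episig.probe_ids)
            except SelectionError:
                failed, score, s = True, 0.0, set()
        jacc = len(s & full_set) / len(s | full_set) if (s | full_set) else 1.0
        rows.append({"case_id": held, "held_out_score": score,
                     "n_probes": len(s), "jaccard_vs_full": jacc,
                     "fold_failed": failed})
    return pd.DataFrame(rows)


def mds_embedding(beta: BetaMatrix, sample_ids: list[str]) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on the signature probes.

    Double-centres the squared Euclidean distance matrix and takes the
    top-two eigenvectors.  Output is centred; orientation is fixed by
    requiring the first sample's coordinate to be non-negative on each
    axis.
    """
    if len(sample_ids) < 3:
        raise EpisignError("MDS needs at least 3 samples")
    X = beta.subset_samples(list(sample_ids)).values.to_numpy(dtype=float).T
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    for axis in range(coords.shape[1]):
        if coords[0, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return pd.DataFrame(coords, index=list(sample_ids), columns=["dim1", "dim2"])


def hierarchical_order(
    beta: BetaMatrix, sample_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Ward/Euclidean agglomerative clustering of samples.

    Samples are clustered in sorted-id order so that equal-height merges
    resolve deterministically (smaller id first); returns the scipy
    linkage matrix and the leaf order as sample ids.
    """
    if len(sample_ids) < 2:
        raise EpisignError("clustering needs at least 2 samples")
    ordered = sorted(sample_ids)
    X = beta.subset_samples(ordered).values.to_numpy(dtype=float).T
    Z = _hier.linkage(X, method="ward", metric="euclidean")
    leaves = _hier.leaves_list(Z)
    return Z, [ordered[i] for i in leaves]
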