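"""Rank-based transcriptional signature classification.

A per-sample signature is the ordered list of the ``n1`` highest- and
``n2`` lowest-ranked probes after a Wilcoxon rank-sum pre-filter.
Samples are compared through a distance built from weighted
Kolmogorov-Smirnov enrichment scores of each sample's signature against
the other sample's full probe ranking, and classified to the group with
the lowest mean distance.  A genetic algorithm tunes (n1, n2,
filter stringency) for cross-validated accuracy with a parsimony
penalty, and the union of all per-sample signatures yields the final
transcriptional biomarker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "ClassifierParams",
    "SampleSignature",
    "CVReport",
    "Biomarker",
    "GASettings",
    "wilcoxon_filter",
    "rank_sample",
    "rank_all_samples",
    "build_signature",
    "enrichment_score",
    "signature_distance",
    "distance_matrix",
    "classify",
    "cross_validate",
    "permutation_test",
    "ga_optimize",
    "extract_biomarker",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Probe x sample abundance matrix with two-group labels.

    Parameters
    ----------
    abundance
        ``(n_probes, n_samples)`` matrix of (log-scale) abundances.
    probe_ids, sample_ids
        Unique identifiers for rows and columns.
    group_labels
        One label per sample; exactly two distinct labels overall.
    probe_to_gene
        Many-to-one map from probe id to gene symbol.
    """

    abundance: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        if len(set(self.group_labels)) != 2:
            raise ValueError("exactly two distinct group labels required")
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundance matrix must be finite")

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, lexicographically sorted."""
        return tuple(sorted(set(self.group_labels)))  # type: ignore[return-value]

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        return ExpressionDataset(
            abundance=self.abundance[:, idx],
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            group_labels=[self.group_labels[i] for i in idx],
            probe_to_gene=dict(self.probe_to_gene),
        )


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable parameters of the signature classifier.

    n1/n2 are the numbers of top/bottom probes in each signature (the
    same for every sample); ``alpha_filter`` is the Wilcoxon pre-filter
    p-value cutoff; ``weight_exponent`` weights the enrichment-score
    hits by |position score|^exponent.
    """

    n1: int = 25
    n2: int = 25
    alpha_filter: float = 0.01
    weight_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if not (0 < self.alpha_filter <= 1):
            raise ValueError("alpha_filter must be in (0, 1]")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be nonnegative")


@dataclass(frozen=True)
class SampleSignature:
    """Top-n1 / bottom-n2 probe lists for one sample.

    ``top`` is ordered highest-ranked first; ``bottom`` keeps the
    ranking order, so its last element is the lowest-ranked probe.
    """

    sample_id: str
    top: tuple[str, ...]
    bottom: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.top) & set(self.bottom):
            raise ValueError("top and bottom signatures overlap")

    @property
    def probes(self) -> set[str]:
        return set(self.top) | set(self.bottom)


@dataclass
class CVReport:
    """Cross-validation outcome: folds, per-fold and summary metrics."""

    fold_assignments: list[int]
    fold_accuracy: list[float]
    fold_precision: list[float]
    fold_recall: list[float]
    params: ClassifierParams
    n_folds: int

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) if len(self.fold_accuracy) > 1 else 0.0

    @property
    def precision(self) -> float:
        return float(np.mean(self.fold_precision))

    @property
    def recall(self) -> float:
        return float(np.mean(self.fold_recall))


@dataclass
class Biomarker:
    """Probes included in at least one sample signature, with genes."""

    probe_ids: set[str]
    gene_symbols: set[str]
    filter_pvalues: dict[str, float]


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

def wilcoxon_filter(
    ds: ExpressionDataset, alpha_filter: float = 0.01
) -> tuple[list[str], dict[str, float]]:
    """Two-sided Wilcoxon rank-sum filter per probe.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.  Probes that are
    constant across both groups get p = 1.  Returns the retained probe
    ids (those with p <= ``alpha_filter``), sorted by probe id, and the
    full probe -> p-value map.
    """
    ga, gb = ds.groups
    mask_a = np.array([g == ga for g in ds.group_labels])
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = ds.abundance[:, mask_a]
    xb = ds.abundance[:, mask_b]

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            xa, xb, axis=1, alternative="two-sided", method="auto"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
    # constant probes: zero rank variance -> undefined statistic -> p = 1
    constant = np.ptp(np.hstack([xa, xb]), axis=1) == 0
    pvals[constant | ~np.isfinite(pvals)] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)

    pmap = dict(zip(ds.probe_ids, pvals.tolist()))
    retained = sorted(p for p, v in pmap.items() if v <= alpha_filter)
    return retained, pmap


# ---------------------------------------------------------------------------
# Per-sample ranking and signatures
# ---------------------------------------------------------------------------

def rank_sample(
    ds: ExpressionDataset, retained: Sequence[str], sample_id: str
) -> list[str]:
    """Probes sorted by descending abundance in one sample.

    Ties are broken by ascending probe id so the ranking is
    deterministic regardless of input row order.
    """
    col = ds.sample_ids.index(sample_id)
    probe_index = {p: i for i, p in enumerate(ds.probe_ids)}
    probes = sorted(retained)
    idx = [probe_index[p] for p in probes]
    values = ds.abundance[idx, col]
    # lexsort: last key is primary; probes pre-sorted so stable sort on
    # -value keeps ascending-id order within ties
    order = np.argsort(-values, kind="stable")
    return [probes[i] for i in order]


def rank_all_samples(
    ds: ExpressionDataset, retained: Sequence[str]
) -> dict[str, list[str]]:
    """Vectorized :func:`rank_sample` for every sample."""
    probes = sorted(retained)
    probe_index = {p: i for i, p in enumerate(ds.probe_ids)}
    idx = np.array([probe_index[p] for p in probes])
    sub = ds.abundance[idx, :]
    out: dict[str, list[str]] = {}
    for j, sid in enumerate(ds.sample_ids):
        order = np.argsort(-sub[:, j], kind="stable")
        out[sid] = [probes[i] for i in order]
    return out


def build_signature(ranked: Sequence[str], n1: int, n2: int) -> SampleSignature:
    """First ``n1`` and last ``n2`` probes of a ranking."""
    if n1 + n2 > len(ranked):
        raise ValueError(
            f"n1+n2 = {n1 + n2} exceeds ranking length {len(ranked)}"
        )
    return SampleSignature(
        sample_id="",
        top=tuple(ranked[:n1]),
        bottom=tuple(ranked[len(ranked) - n2:]),
    )


def _signature_for_sample(
    sample_id: str, ranked: Sequence[str], n1: int, n2: int
) -> SampleSignature:
    sig = build_signature(ranked, n1, n2)
    return SampleSignature(sample_id=sample_id, top=sig.top, bottom=sig.bottom)


# ---------------------------------------------------------------------------
# Weighted enrichment score and signature distance
# ---------------------------------------------------------------------------

def _position_scores(n: int) -> np.ndarray:
    """Linear position score from +1 (top of ranking) to -1 (bottom)."""
    if n == 1:
        return np.array([1.0])
    return 1.0 - 2.0 * np.arange(n) / (n - 1)


def enrichment_score(
    hit_set: Sequence[str], ranking: Sequence[str], weight_exponent: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Walking down ``ranking``, the running sum gains
    ``|position score|^weight_exponent`` (normalized) at each member of
    ``hit_set`` and loses ``1/(n_misses)`` elsewhere; the score is the
    deviation of largest magnitude, in [-1, 1].  +1 means the set sits
    exactly at the top of the ranking, -1 exactly at the bottom.
    """
    n = len(ranking)
    hits = set(hit_set)
    if not hits:
        raise ValueError("empty hit set")
    if not hits <= set(ranking):
        raise ValueError("hit set contains probes outside the ranking")
    k = len(hits)
    if k == n:
        return 1.0  # every position is a hit: running sum climbs to +1
    w = np.abs(_position_scores(n)) ** weight_exponent
    is_hit = np.fromiter((p in hits for p in ranking), bool, count=n)
    hit_w = np.where(is_hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit weights zero (exponent on a zero score)
        hit_w = is_hit.astype(float)
        total = float(k)
    running = np.cumsum(hit_w / total - (~is_hit) / (n - k))
    return _signed_max_deviation(running)


def signature_distance(
    sig_a: SampleSignature,
    sig_b: SampleSignature,
    ranked_a: Sequence[str],
    ranked_b: Sequence[str],
    weight_exponent: float = 1.0,
) -> float:
    """Enrichment-score distance between two samples, in [0, 1].

    Cross-evaluates each signature against the other sample's ranking:

        s = ES(top_A | R_B) - ES(bot_A | R_B)
          + ES(top_B | R_A) - ES(bot_B | R_A)      (s in [-4, 4])
        d = 1 - (s + 4) / 8

    Identical rankings give d = 0; perfectly anti-correlated rankings
    (each top signature at the bottom of the other ranking and vice
    versa) give d = 1.  Symmetric by construction.
    """
    if set(ranked_a) != set(ranked_b):
        raise ValueError("signatures built from different probe universes")
    s = (
        enrichment_score(sig_a.top, ranked_b, weight_exponent)
        - enrichment_score(sig_a.bottom, ranked_b, weight_exponent)
        + enrichment_score(sig_b.top, ranked_a, weight_exponent)
        - enrichment_score(sig_b.bottom, ranked_a, weight_exponent)
    )
    return float(1.0 - (s + 4.0) / 8.0)


def _signed_max_deviation(cand: np.ndarray, tol: float = 1e-12) -> float:
    """Deviation of largest magnitude; near-ties resolve to the positive
    side so the sign does not depend on floating-point summation order."""
    max_pos = max(float(cand.max(initial=0.0)), 0.0)
    min_neg = min(float(cand.min(initial=0.0)), 0.0)
    if max_pos >= -min_neg - tol:
        return max_pos
    return min_neg


def _es_from_positions(pos: np.ndarray, n: int, w: np.ndarray) -> float:
    """Enrichment score from sorted 0-based hit positions (fast path).

    The running sum is piecewise linear with extrema only at hit
    positions (just before and at each hit), so only 2k candidates need
    checking.  ``w`` are the position weights.
    """
    k = pos.size
    if k == n:
        return 1.0
    hit_w = w[pos]
    total = hit_w.sum()
    if total == 0:
        hit_w = np.ones(k)
        total = float(k)
    cum_hit = np.cumsum(hit_w) / total
    # misses strictly before each hit position
    miss_before = (pos - np.arange(k)) / (n - k)
    # deviation just before hit j (all previous hits counted, miss run ends)
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before
    # deviation at hit j
    dev_at = cum_hit - miss_before
    # the trailing miss run only decays back toward 0, so the extrema are
    # fully covered by the before/at-hit candidates
    cand = np.concatenate([dev_before, dev_at])
    return _signed_max_deviation(cand)


def distance_matrix(
    rankings: Mapping[str, Sequence[str]],
    signatures: Mapping[str, SampleSignature],
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """All-to-all signature distance matrix.

    Symmetric with zero diagonal, entries in [0, 1]; rows/columns follow
    the iteration order of ``rankings``.
    """
    sample_ids = list(rankings)
    n_samples = len(sample_ids)
    universe = sorted(next(iter(rankings.values())))
    p_index = {p: i for i, p in enumerate(universe)}
    n = len(universe)
    w = np.abs(_position_scores(n)) ** weight_exponent

    # position of each probe within each sample's ranking
    pos_of = {}
    for sid in sample_ids:
        r = rankings[sid]
        if len(r) != n or set(r) != set(universe):
            raise ValueError("rankings disagree on the probe universe")
        arr = np.empty(n, dtype=int)
        for pos, probe in enumerate(r):
            arr[p_index[probe]] = pos
        pos_of[sid] = arr

    top_idx = {
        sid: np.array([p_index[p] for p in signatures[sid].top])
        for sid in sample_ids
    }
    bot_idx = {
        sid: np.array([p_index[p] for p in signatures[sid].bottom])
        for sid in sample_ids
    }

    d = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            a, b = sample_ids[i], sample_ids[j]
            s = (
                _es_from_positions(np.sort(pos_of[b][top_idx[a]]), n, w)
                - _es_from_positions(np.sort(pos_of[b][bot_idx[a]]), n, w)
                + _es_from_positions(np.sort(pos_of[a][top_idx[b]]), n, w)
                - _es_from_positions(np.sort(pos_of[a][bot_idx[b]]), n, w)
            )
            d[i, j] = d[j, i] = 1.0 - (s + 4.0) / 8.0

    assert np.all((d >= -1e-12) & (d <= 1 + 1e-12)), "distance out of [0,1]"
    np.clip(d, 0.0, 1.0, out=d)
    return pd.DataFrame(d, index=sample_ids, columns=sample_ids)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    distances_to_training: Mapping[str, float],
    training_labels: Mapping[str, str],
) -> tuple[str, bool]:
    """Nearest-group-centroid rule on mean signature distance.

    Returns ``(label, tie_flag)``; ties go to the lexicographically
    smaller label and are flagged.
    """
    groups = sorted(set(training_labels.values()))
    if len(groups) != 2:
        raise ValueError("training set must contain exactly two groups")
    means = {
        g: float(
            np.mean([distances_to_training[s] for s, l in training_labels.items() if l == g])
        )
        for g in groups
    }
    if means[groups[0]] == means[groups[1]]:
        return groups[0], True
    return min(groups, key=lambda g: means[g]), False


def _fit_predict(
    train: ExpressionDataset,
    test: ExpressionDataset,
    params: ClassifierParams,
) -> list[str]:
    """Fit the filter/signatures on ``train`` only and classify ``test``."""
    retained, _ = wilcoxon_filter(train, params.alpha_filter)
    retained = _ensure_enough_probes(train, retained, params)
    combined_ids = train.sample_ids + test.sample_ids
    rankings: dict[str, list[str]] = {}
    rankings.update(rank_all_samples(train, retained))
    rankings.update(rank_all_samples(test, retained))
    sigs = {
        sid: _signature_for_sample(sid, rankings[sid], params.n1, params.n2)
        for sid in combined_ids
    }
    dmat = distance_matrix(rankings, sigs, params.weight_exponent)
    train_labels = dict(zip(train.sample_ids, train.group_labels))
    preds = []
    for sid in test.sample_ids:
        dist = {t: float(dmat.loc[sid, t]) for t in train.sample_ids}
        label, _ = classify(dist, train_labels)
        preds.append(label)
    return preds


def _ensure_enough_probes(
    ds: ExpressionDataset, retained: list[str], params: ClassifierParams
) -> list[str]:
    """Top up the retained list by smallest p when the filter is too strict."""
    need = params.n1 + params.n2
    if len(retained) >= need:
        return retained
    _, pmap = wilcoxon_filter(ds, 1.0)
    ranked = sorted(pmap, key=lambda p: (pmap[p], p))
    extra = [p for p in ranked if p not in set(retained)]
    out = sorted(set(retained) | set(extra[: need - len(retained)]))
    logger.warning(
        "filter retained %d probes < n1+n2 = %d; topped up by smallest p",
        len(retained), need,
    )
    return out


def _binary_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], groups: tuple[str, str]
) -> tuple[float, float, float]:
    """Accuracy and macro-averaged precision/recall over the two groups."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    acc = float(np.mean(yt == yp))
    precs, recs = [], []
    for g in groups:
        tp = np.sum((yp == g) & (yt == g))
        fp = np.sum((yp == g) & (yt != g))
        fn = np.sum((yp != g) & (yt == g))
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
    return acc, float(np.mean(precs)), float(np.mean(recs))


def cross_validate(
    ds: ExpressionDataset,
    params: ClassifierParams,
    n_folds: int = 10,
    seed: int | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation with in-fold refitting.

    The Wilcoxon filter and the signatures are re-fit inside each
    training fold only, so no test-fold information leaks into probe
    selection.  If the smaller group has fewer members than ``n_folds``
    the fold count is reduced with a warning.
    """
    if seed is None:
        seed = params.seed
    labels = np.asarray(ds.group_labels)
    smallest = min(np.sum(labels == g) for g in ds.groups)
    if smallest < n_folds:
        logger.warning(
            "group of size %d smaller than %d folds; using %d folds",
            smallest, n_folds, smallest,
        )
        n_folds = int(smallest)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assign = np.empty(len(ds.sample_ids), dtype=int)
    accs, precs, recs = [], [], []
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_assign[te] = k
        preds = _fit_predict(ds.subset_samples(tr), ds.subset_samples(te), params)
        a, p, r = _binary_metrics(labels[te].tolist(), preds, ds.groups)
        accs.append(a)
        precs.append(p)
        recs.append(r)
    return CVReport(
        fold_assignments=fold_assign.tolist(),
        fold_accuracy=accs,
        fold_precision=precs,
        fold_recall=recs,
        params=params,
        n_folds=n_folds,
    )


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _loo_accuracy(ds: ExpressionDataset, params: ClassifierParams) -> float:
    """Leave-one-out accuracy on the full-data distance matrix.

    The filter is fit on all samples; each sample is then classified
    against the others.  Fast enough to repeat thousands of times, which
    is what the permutation test needs.
    """
    retained, _ = wilcoxon_filter(ds, params.alpha_filter)
    retained = _ensure_enough_probes(ds, retained, params)
    rankings = rank_all_samples(ds, retained)
    sigs = {
        sid: _signature_for_sample(sid, rankings[sid], params.n1, params.n2)
        for sid in ds.sample_ids
    }
    dmat = distance_matrix(rankings, sigs, params.weight_exponent)
    labels = dict(zip(ds.sample_ids, ds.group_labels))
    correct = 0
    for sid in ds.sample_ids:
        train_labels = {s: l for s, l in labels.items() if s != sid}
        dist = {s: float(dmat.loc[sid, s]) for s in train_labels}
        pred, _ = classify(dist, train_labels)
        correct += pred == labels[sid]
    return correct / len(ds.sample_ids)


def permutation_test(
    ds: ExpressionDataset,
    params: ClassifierParams,
    n_perm: int = 10000,
    seed: int = 0,
    unit: str = "samples",
    statistic: Callable[[ExpressionDataset, ClassifierParams], float] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Empirical p-value for the classification accuracy.

    ``unit="samples"`` permutes the group labels; ``unit="probes"``
    shuffles probe values independently within each sample, destroying
    the cross-sample rank structure.  Returns
    ``(p, observed, permuted_accuracies)`` with the add-one estimator
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if unit not in ("samples", "probes"):
        raise ValueError("unit must be 'samples' or 'probes'")
    stat = statistic or _loo_accuracy
    rng = np.random.default_rng(seed)
    observed = stat(ds, params)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        if unit == "samples":
            perm_labels = rng.permutation(ds.group_labels).tolist()
            perm_ds = ExpressionDataset(
                ds.abundance, ds.probe_ids, ds.sample_ids, perm_labels,
                ds.probe_to_gene,
            )
        else:
            shuffled = ds.abundance.copy()
            for j in range(shuffled.shape[1]):
                shuffled[:, j] = rng.permutation(shuffled[:, j])
            perm_ds = ExpressionDataset(
                shuffled, ds.probe_ids, ds.sample_ids, ds.group_labels,
                ds.probe_to_gene,
            )
        perm_stats[b] = stat(perm_ds, params)
    p = (1 + int(np.sum(perm_stats >= observed))) / (1 + n_perm)
    return float(p), float(observed), perm_stats


# ---------------------------------------------------------------------------
# Genetic-algorithm parameter optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GASettings:
    """Genetic-algorithm hyperparameters (desk-scale defaults)."""

    population: int = 40
    generations: int = 25
    tournament: int = 3
    crossover_prob: float = 0.7
    mutation_prob: float = 0.1
    elitism: int = 1
    lambda_len: float = 0.01


def ga_optimize(
    ds: ExpressionDataset,
    n1_grid: Sequence[int],
    n2_grid: Sequence[int],
    alpha_grid: Sequence[float],
    settings: GASettings | None = None,
    n_folds: int = 10,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[ClassifierParams, CVReport, list[dict]]:
    """Tune (n1, n2, alpha_filter) by a genetic algorithm.

    Fitness is mean CV accuracy minus a parsimony penalty
    ``lambda_len * (n1 + n2) / P`` with P the retained probe count at
    that stringency, so among equally accurate settings the shortest
    signature wins.  Individuals are index triples into the candidate
    grids; selection is by tournament, recombination by uniform
    crossover, mutation resamples one grid index.  Deterministic for a
    fixed seed.  Returns the best parameters, their CV report and the
    per-generation log.
    """
    settings = settings or GASettings()
    grids = [list(n1_grid), list(n2_grid), list(alpha_grid)]
    if any(len(g) == 0 for g in grids):
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, int, int], tuple[float, CVReport]] = {}

    def evaluate(ind: tuple[int, int, int]) -> float:
        if ind in cache:
            return cache[ind][0]
        n1, n2, alpha = grids[0][ind[0]], grids[1][ind[1]], grids[2][ind[2]]
        params = ClassifierParams(
            n1=n1, n2=n2, alpha_filter=alpha,
            weight_exponent=weight_exponent, seed=seed,
        )
        retained, _ = wilcoxon_filter(ds, alpha)
        n_retained = max(len(retained), n1 + n2)
        report = cross_validate(ds, params, n_folds=n_folds, seed=seed)
        fitness = report.accuracy - settings.lambda_len * (n1 + n2) / n_retained
        cache[ind] = (fitness, report)
        return fitness

    def random_ind() -> tuple[int, int, int]:
        return tuple(int(rng.integers(len(g))) for g in grids)  # type: ignore[return-value]

    pop = [random_ind() for _ in range(settings.population)]
    log: list[dict] = []
    for gen in range(settings.generations):
        fits = [evaluate(ind) for ind in pop]
        order = np.argsort(fits)[::-1]
        best = pop[order[0]]
        log.append(
            {
                "generation": gen,
                "best_fitness": fits[order[0]],
                "mean_fitness": float(np.mean(fits)),
                "best_individual": best,
            }
        )
        next_pop = [pop[order[i]] for i in range(settings.elitism)]
        while len(next_pop) < settings.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(len(pop), size=settings.tournament)
                parents.append(pop[max(contenders, key=lambda i: fits[i])])
            child = list(parents[0])
            if rng.random() < settings.crossover_prob:
                for k in range(3):
                    if rng.random() < 0.5:
                        child[k] = parents[1][k]
            for k in range(3):
                if rng.random() < settings.mutation_prob:
                    child[k] = int(rng.integers(len(grids[k])))
            next_pop.append(tuple(child))
        pop = next_pop

    fits = [evaluate(ind) for ind in pop]
    all_evaluated = sorted(cache.items(), key=lambda kv: -kv[1][0])
    best_ind, (best_fit, best_report) = all_evaluated[0]
    best_params = ClassifierParams(
        n1=grids[0][best_ind[0]],
        n2=grids[1][best_ind[1]],
        alpha_filter=grids[2][best_ind[2]],
        weight_exponent=weight_exponent,
        seed=seed,
    )
    log.append({"generation": settings.generations, "best_fitness": best_fit,
                "mean_fitness": float(np.mean(fits)), "best_individual": best_ind})
    return best_params, best_report, log


# ---------------------------------------------------------------------------
# Biomarker extraction
# ---------------------------------------------------------------------------

def extract_biomarker(
    signatures: Sequence[SampleSignature],
    probe_to_gene: Mapping[str, str],
    pvalue_map: Mapping[str, float],
) -> Biomarker:
    """Union of all per-sample signatures, mapped to gene symbols."""
    probes: set[str] = set()
    for sig in signatures:
        probes |= sig.probes
    genes = {probe_to_gene[p] for p in probes if p in probe_to_gene}
    missing = [p for p in probes if p not in probe_to_gene]
    if missing:
        logger.warning("%d biomarker probes lack a gene mapping", len(missing))
    return Biomarker(
        probe_ids=probes,
        gene_symbols=genes,
        filter_pvalues={p: float(pvalue_map[p]) for p in probes if p in pvalue_map},
    )


def fit_signatures(
    ds: ExpressionDataset, params: ClassifierParams
) -> tuple[list[SampleSignature], dict[str, float], list[str]]:
    """Convenience: filter, rank and build every sample's signature."""
    retained, pmap = wilcoxon_filter(ds, params.alpha_filter)
    retained = _ensure_enough_probes(ds, retained, params)
    rankings = rank_all_samples(ds, retained)
    sigs = [
        _signature_for_sample(sid, rankings[sid], params.n1, params.n2)
        for sid in ds.sample_ids
    ]
    return sigs, pmap, retained
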