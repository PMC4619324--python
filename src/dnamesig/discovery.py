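"""Signature discovery: rank CpGs, select a signature size by cross-validation.

A signature is discovered in three steps.  First every probe is tested for a
group difference in beta between marker-positive and marker-negative samples
(Welch's t by default, Wilcoxon rank-sum behind a flag) and the probes are
ranked by p-value, with Benjamini-Hochberg q-values estimating the FDR at any
ranking cut.  Second, the signature *size* is chosen by stratified k-fold
cross-validation: within each training fold the probes are re-ranked, the
top-``size`` training deltas form a template, and held-out samples are scored
by correlating their profile with the template; the size with the best mean
held-out AUC for the marker label wins (ties go to the smaller, cheaper
signature).  Third, the final signature is refit on the full cohort at the
chosen size.

The top of a relaxed ranking can also be partitioned into hyper- and
hypomethylated probes (delta sign) for direction-specific enrichment tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .cohort_io import Cohort, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AssociationRanking:
    """Per-probe association with the marker, sorted by p ascending.

    ``table`` columns: probe_id, statistic, p, q, mean_pos, mean_neg, delta,
    rank (1-based).  Ties in p are broken by |delta| descending, then
    probe_id lexicographic, so the ranking is reproducible.
    """

    table: pd.DataFrame
    test: str = "welch"
    skipped_probes: list[str] = field(default_factory=list)

    def top(self, n: int) -> pd.DataFrame:
        return self.table.head(n)


@dataclass
class MethylationSignature:
    """An ordered probe set with direction weights (the delta template).

    ``weights[i] = mean_pos[i] - mean_neg[i]`` on the discovery cohort, so a
    sample that correlates positively with the weights resembles the
    marker-positive centroid.
    """

    probe_ids: list[str]
    weights: np.ndarray
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    fdr_at_size: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mean_pos = np.asarray(self.mean_pos, dtype=float)
        self.mean_neg = np.asarray(self.mean_neg, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("signature probes must be unique")
        if not (len(self.probe_ids) == len(self.weights) == len(self.mean_pos) == len(self.mean_neg)):
            raise ValidationError("signature field lengths differ")
        if np.any(self.weights == 0):
            raise ValidationError("signature weights must be non-zero")

    @property
    def size(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "weight": self.weights,
                "mean_pos": self.mean_pos,
                "mean_neg": self.mean_neg,
                "rank": np.arange(1, self.size + 1),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "MethylationSignature":
        t = pd.read_csv(Path(path), sep="\t")
        return cls(
            probe_ids=list(t["probe_id"].astype(str)),
            weights=t["weight"].to_numpy(),
            mean_pos=t["mean_pos"].to_numpy(),
            mean_neg=t["mean_neg"].to_numpy(),
        )


def _group_matrices(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    mask = cohort.marker_mask()
    neg = np.array([s.marker_status == "negative" for s in cohort.samples])
    return cohort.beta.values[:, mask], cohort.beta.values[:, neg]


def _welch_vectorized(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t statistic and two-sided p per probe (rows), NaN-aware.

    Degenerate probes (both group variances zero) get t = 0, p = 1 when the
    means agree and t = +/-inf, p = 0 when they differ.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = np.isfinite(pos).sum(axis=1)
        n2 = np.isfinite(neg).sum(axis=1)
        m1, m2 = np.nanmean(pos, axis=1), np.nanmean(neg, axis=1)
        v1, v2 = np.nanvar(pos, axis=1, ddof=1), np.nanvar(neg, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        degenerate = se2 == 0.0
        same = degenerate & (m1 == m2)
        diff = degenerate & (m1 != m2)
        t[same], p[same] = 0.0, 1.0
        t[diff] = np.where(m1[diff] > m2[diff], np.inf, -np.inf)
        p[diff] = 0.0
    return t, p


def rank_cpgs(cohort: Cohort, test: Literal["welch", "wilcoxon"] = "welch") -> AssociationRanking:
    """Rank every probe by its marker association.

    Probes with missing values are tested on the available values when each
    group retains at least two; otherwise they are skipped (and logged).
    q-values are Benjamini-Hochberg over the tested probes.
    """
    pos_m, neg_m = _group_matrices(cohort)
    if pos_m.shape[1] < 2 or neg_m.shape[1] < 2:
        raise ValidationError(
            f"need >= 2 samples per marker group, got {pos_m.shape[1]} positive / "
            f"{neg_m.shape[1]} negative"
        )
    probes = np.array(cohort.beta.probe_ids)
    usable = (np.isfinite(pos_m).sum(axis=1) >= 2) & (np.isfinite(neg_m).sum(axis=1) >= 2)
    skipped = list(probes[~usable])
    if skipped:
        logger.info("rank_cpgs: skipped %d probes with <2 usable values per group", len(skipped))
    pos_m, neg_m, probes = pos_m[usable], neg_m[usable], probes[usable]
    if test == "welch":
        stat, p = _welch_vectorized(pos_m, neg_m)
    else:
        stat = np.empty(len(probes))
        p = np.empty(len(probes))
        for j in range(len(probes)):
            a = pos_m[j][np.isfinite(pos_m[j])]
            b = neg_m[j][np.isfinite(neg_m[j])]
            stat[j], p[j] = stats.mannwhitneyu(a, b, alternative="two-sided")
    with np.errstate(invalid="ignore"):
        mean_pos = np.nanmean(pos_m, axis=1)
        mean_neg = np.nanmean(neg_m, axis=1)
    table = pd.DataFrame(
        {
            "probe_id": probes,
            "statistic": stat,
            "p": p,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "delta": mean_pos - mean_neg,
        }
    )
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["abs_delta"] = table["delta"].abs()
    table = (
        table.sort_values(["p", "abs_delta", "probe_id"], ascending=[True, False, True])
        .drop(columns="abs_delta")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return AssociationRanking(table=table, test=test, skipped_probes=skipped)


def signature_from_ranking(
    ranking: AssociationRanking, size: int, provenance: dict | None = None
) -> MethylationSignature:
    """Freeze the top-``size`` probes of a ranking into a signature."""
    top = ranking.table[ranking.table["delta"] != 0].head(size)
    return MethylationSignature(
        probe_ids=list(top["probe_id"]),
        weights=top["delta"].to_numpy(),
        mean_pos=top["mean_pos"].to_numpy(),
        mean_neg=top["mean_neg"].to_numpy(),
        fdr_at_size=float(top["q"].iloc[-1]) if len(top) else None,
        provenance=provenance or {},
    )


def select_signature_cv(
    cohort: Cohort,
    candidate_sizes: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    test: Literal["welch", "wilcoxon"] = "welch",
) -> MethylationSignature:
    """Choose the signature size by stratified k-fold cross-validation.

    Within each fold, probes are re-ranked on the training samples alone and
    a delta template of each candidate size scores the held-out samples; the
    per-size criterion is the mean held-out AUC for marker status.  The best
    size (ties -> smallest) is refit on the full cohort.  ``fdr_at_size`` is
    the q-value of the size-th ranked probe on the full fit.
    """
    from .scoring import correlation_score  # local import to avoid a cycle

    if not candidate_sizes:
        raise ValidationError("candidate_sizes must be non-empty")
    labels = cohort.marker_mask().astype(int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    eff_folds = min(folds, n_pos, n_neg)
    if eff_folds < folds:
        logger.warning("reducing folds from %d to %d (smallest group size)", folds, eff_folds)
    if eff_folds < 2:
        raise ValidationError("need >= 2 samples per group for cross-validation")

    sizes = sorted(set(int(s) for s in candidate_sizes))
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    aucs: dict[int, list[float]] = {s: [] for s in sizes}
    sample_ids = np.array(cohort.beta.sample_ids)
    for train_idx, test_idx in skf.split(sample_ids, labels):
        train = cohort.subset(list(sample_ids[train_idx]))
        ranking = rank_cpgs(train, test=test)
        for size in sizes:
            sig = signature_from_ranking(ranking, size)
            scores, ok = [], []
            for i in test_idx:
                profile = dict(zip(cohort.beta.probe_ids, cohort.beta.values[:, i]))
                sc = correlation_score(profile, sig)
                if sc.score is not None:
                    scores.append(sc.score)
                    ok.append(labels[i])
            if len(set(ok)) == 2:
                aucs[size].append(roc_auc_score(ok, scores))
    mean_auc = {s: (float(np.mean(v)) if v else np.nan) for s, v in aucs.items()}
    if all(np.isnan(a) for a in mean_auc.values()):
        raise ValidationError("AUC undefined for every candidate size (single-class folds)")
    best = max(sizes, key=lambda s: (np.nan_to_num(mean_auc[s], nan=-1.0), -s))

    full_ranking = rank_cpgs(cohort, test=test)
    sig = signature_from_ranking(
        full_ranking,
        best,
        provenance={
            "candidate_sizes": sizes,
            "folds": eff_folds,
            "seed": seed,
            "test": test,
            "mean_cv_auc": {str(s): mean_auc[s] for s in sizes},
            "selected_size": best,
        },
    )
    logger.info("selected signature size %d (mean CV AUC %.3f)", best, mean_auc[best])
    return sig


def partition_by_direction(
    ranking: AssociationRanking, top_n: int, fdr_max: float
) -> tuple[list[str], list[str]]:
    """Split the top-``top_n`` ranked probes passing FDR into hyper/hypo lists.

    Probes with q >= fdr_max are dropped; delta > 0 -> hypermethylated in
    marker-positives, delta < 0 -> hypomethylated.
    """
    if top_n > len(ranking.table):
        raise ValidationError(f"top_n={top_n} exceeds {len(ranking.table)} tested probes")
    top = ranking.table.head(top_n)
    kept = top[top["q"] < fdr_max]
    hyper = list(kept.loc[kept["delta"] > 0, "probe_id"])
    hypo = list(kept.loc[kept["delta"] < 0, "probe_id"])
    return hyper, hypo
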