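"""Single-sample correlation scores, frozen cutoffs, and random-signature nulls.

A discovered signature doubles as a classifier: correlate its delta template
(mean_pos - mean_neg per probe) with a sample's beta values over the
signature probes and the resulting Pearson correlation in [-1, 1] is the
sample's score — positive means the sample resembles the marker-positive
centroid.  Because the score only needs the probes the sample actually has,
it transfers across array platforms (a 27k-derived signature scores 450k
samples via the probe-id intersection) and tolerates sporadic missingness
down to a coverage floor.

A cutoff frozen on the discovery cohort (chosen by ROC analysis to balance
sensitivity and specificity) turns scores into high/low calls that can be
applied unchanged to independent cohorts.  To show an observed survival
association is a property of the signature rather than of scoring per se,
``random_signature_null`` rebuilds size-matched random signatures from the
discovery cohort and records the survival statistic each achieves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort, ValidationError
from .discovery import MethylationSignature

logger = logging.getLogger(__name__)


@dataclass
class SignatureScore:
    """One sample's correlation with the signature template.

    ``score`` is None (and ``call`` = ``"unscored"``) when too few signature
    probes are present or a vector is constant over the intersection.
    """

    sample_id: str
    score: float | None
    n_probes_used: int
    call: Literal["high", "low", "unscored", "uncalled"] = "uncalled"
    reason: str | None = None


@dataclass
class ScoreCutoff:
    """A frozen score threshold with the discovery-set operating point."""

    threshold: float
    sensitivity: float
    specificity: float
    method: str = "max_min_sens_spec"

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "method": self.method,
            },
            indent=2,
        )

    @classmethod
    def read(cls, path: str | Path) -> "ScoreCutoff":
        d = json.loads(Path(path).read_text())
        return cls(d["threshold"], d["sensitivity"], d["specificity"], d.get("method", ""))


@dataclass
class NullDistribution:
    """Empirical null of a statistic over random size-matched signatures."""

    draws: np.ndarray
    observed: float
    seed: int
    statistic: str = "cox_abs_z"

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def empirical_p(self) -> float:
        return (1 + int(np.sum(self.draws >= self.observed))) / (self.n_draws + 1)


def correlation_score(
    sample_profile: Mapping[str, float],
    signature: MethylationSignature,
    min_coverage: float = 0.8,
    method: Literal["pearson", "spearman"] = "pearson",
) -> SignatureScore:
    """Correlate one sample's beta profile with the signature template.

    The correlation runs over the intersection of signature probes with the
    sample's non-missing values; below ``min_coverage`` x signature size the
    sample is left unscored rather than scored on too thin a probe set.
    """
    if signature.size == 0:
        raise ValidationError("signature is empty")
    sid = getattr(sample_profile, "name", "sample")
    xs, ys = [], []
    for probe, w in zip(signature.probe_ids, signature.weights):
        v = sample_profile.get(probe)
        if v is not None and np.isfinite(v):
            xs.append(w)
            ys.append(float(v))
    n_used = len(ys)
    if n_used < min_coverage * signature.size or n_used < 3:
        return SignatureScore(sid, None, n_used, "unscored", reason="coverage below threshold")
    x, y = np.asarray(xs), np.asarray(ys)
    if x.std() == 0.0 or y.std() == 0.0:
        return SignatureScore(sid, None, n_used, "unscored", reason="zero variance")
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return SignatureScore(sid, float(r), n_used)


def score_cohort(
    cohort: Cohort,
    signature: MethylationSignature,
    cutoff: ScoreCutoff | None = None,
    min_coverage: float = 0.8,
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[SignatureScore]:
    """Score every sample of a cohort; optionally apply a frozen cutoff.

    Cross-platform transfer happens here: only the signature probes present
    in the cohort are used.  If the median per-sample coverage falls below
    ``min_coverage`` the platforms are too dissimilar and an error is raised.
    """
    present = {p: i for i, p in enumerate(cohort.beta.probe_ids)}
    keep = [k for k, p in enumerate(signature.probe_ids) if p in present]
    if not keep:
        raise ValidationError("cohort shares no probes with the signature")
    logger.info(
        "score_cohort: %d/%d signature probes present in cohort %s",
        len(keep), signature.size, cohort.name,
    )
    if method == "spearman":
        frame = cohort.beta.to_frame()
        scores = []
        for sid in cohort.beta.sample_ids:
            sc = correlation_score(frame[sid].to_dict(), signature, min_coverage, method)
            sc.sample_id = sid
            scores.append(sc)
    else:
        scores = _pearson_scores_vectorized(cohort, signature, keep, present, min_coverage)
    coverages = [s.n_probes_used for s in scores]
    if np.median(coverages) < min_coverage * signature.size:
        raise ValidationError(
            f"median signature coverage {np.median(coverages):.0f}/{signature.size} is below "
            f"{min_coverage:.0%}: probable platform mismatch between signature and cohort"
        )
    if cutoff is not None:
        for s in scores:
            if s.score is not None:
                s.call = "high" if s.score >= cutoff.threshold else "low"
    return scores


def _pearson_scores_vectorized(
    cohort: Cohort,
    signature: MethylationSignature,
    keep: list[int],
    present: Mapping[str, int],
    min_coverage: float,
) -> list[SignatureScore]:
    """Column-wise masked Pearson correlation of samples with the template."""
    w = signature.weights[keep]
    rows = [present[signature.probe_ids[k]] for k in keep]
    Y = cohort.beta.values[rows, :]  # shared probes x samples
    m = np.isfinite(Y)
    Y0 = np.where(m, Y, 0.0)
    n = m.sum(axis=0)
    sw = w @ m
    sww = (w**2) @ m
    sy = Y0.sum(axis=0)
    syy = (Y0**2).sum(axis=0)
    swy = w @ Y0
    with np.errstate(invalid="ignore", divide="ignore"):
        var_w = n * sww - sw**2
        var_y = n * syy - sy**2
        r = (n * swy - sw * sy) / np.sqrt(var_w * var_y)
    scores: list[SignatureScore] = []
    floor = max(min_coverage * signature.size, 3)
    for i, sid in enumerate(cohort.beta.sample_ids):
        if n[i] < floor:
            scores.append(SignatureScore(sid, None, int(n[i]), "unscored", "coverage below threshold"))
        elif var_w[i] <= 0 or var_y[i] <= 0:
            scores.append(SignatureScore(sid, None, int(n[i]), "unscored", "zero variance"))
        else:
            scores.append(SignatureScore(sid, float(np.clip(r[i], -1.0, 1.0)), int(n[i])))
    return scores


def scores_frame(scores: Sequence[SignatureScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "score": [s.score for s in scores],
            "n_probes_used": [s.n_probes_used for s in scores],
            "call": [s.call for s in scores],
        }
    )


def optimize_cutoff(
    scores: Sequence[SignatureScore],
    labels: Sequence[bool],
    target_sens: float = 0.8,
    target_spec: float = 0.8,
) -> ScoreCutoff:
    """Choose a score threshold by ROC analysis on labelled discovery samples.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus -inf/+inf; a sample is called high when score >=
    threshold.  The rule maximizes min(sensitivity, specificity) — the
    operating point that balances the two — breaking ties by the larger
    sensitivity + specificity, then by the lower threshold.  A warning is
    logged if the achieved operating point misses the targets.
    """
    pairs = [(s.score, bool(l)) for s, l in zip(scores, labels) if s.score is not None]
    if not pairs:
        raise ValidationError("no scored samples")
    y = np.array([l for _, l in pairs])
    x = np.array([v for v, _ in pairs])
    if y.all() or not y.any():
        raise ValidationError("cutoff optimization needs both marker classes among scored samples")
    distinct = np.unique(x)
    candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]))
    best: tuple[float, float, float] | None = None
    best_thr = None
    n_pos, n_neg = y.sum(), (~y).sum()
    for thr in candidates:
        call = x >= thr
        sens = (call & y).sum() / n_pos
        spec = (~call & ~y).sum() / n_neg
        key = (min(sens, spec), sens + spec, -thr)
        if best is None or key > best:
            best = key
            best_thr = (thr, sens, spec)
    thr, sens, spec = best_thr
    if sens < target_sens or spec < target_spec:
        logger.warning(
            "cutoff achieves sens %.2f / spec %.2f, below targets %.2f / %.2f",
            sens, spec, target_sens, target_spec,
        )
    return ScoreCutoff(float(thr), float(sens), float(spec))


def random_signature_null(
    cohort: Cohort,
    signature: MethylationSignature,
    discovery: Cohort,
    n_draws: int = 1000,
    seed: int = 0,
    statistic: Literal["cox_abs_z"] = "cox_abs_z",
    min_coverage: float = 0.8,
) -> NullDistribution:
    """Empirical null for the signature's survival association.

    Each draw picks ``signature.size`` probes uniformly without replacement
    from the probes shared by the discovery and evaluation cohorts, rebuilds
    a delta-weight signature from the discovery group means, scores the
    evaluation cohort, and records |z| of the score coefficient in a
    univariate Cox fit.  ``empirical_p`` = (1 + #draws >= observed) /
    (n_draws + 1).
    """
    from .survival import cox_fit  # local import to avoid a cycle

    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")

    def _stat(scores: Sequence[SignatureScore]) -> float:
        rows = [
            (s.score, samp.time, samp.event)
            for s, samp in zip(scores, cohort.samples)
            if s.score is not None and samp.time is not None and samp.event is not None
        ]
        df = pd.DataFrame(rows, columns=["score", "time", "event"])
        fit = cox_fit(df["time"], df["event"], df[["score"]])
        return abs(fit.table.loc["score", "z"])

    observed = _stat(score_cohort(cohort, signature, min_coverage=min_coverage))

    shared = sorted(set(discovery.beta.probe_ids) & set(cohort.beta.probe_ids))
    if len(shared) < signature.size:
        raise ValidationError("fewer shared probes than the signature size")
    rng = np.random.default_rng(seed)
    disc_pos, disc_neg = (
        discovery.beta.values[:, discovery.marker_mask()],
        discovery.beta.values[:, [s.marker_status == "negative" for s in discovery.samples]],
    )
    probe_index = {p: i for i, p in enumerate(discovery.beta.probe_ids)}
    draws = np.empty(n_draws)
    for d in range(n_draws):
        chosen = rng.choice(len(shared), size=signature.size, replace=False)
        probes = [shared[i] for i in chosen]
        idx = [probe_index[p] for p in probes]
        with np.errstate(invalid="ignore"):
            mp = np.nanmean(disc_pos[idx], axis=1)
            mn = np.nanmean(disc_neg[idx], axis=1)
        w = mp - mn
        keep = w != 0
        rand_sig = MethylationSignature(
            probe_ids=[p for p, k in zip(probes, keep) if k],
            weights=w[keep], mean_pos=mp[keep], mean_neg=mn[keep],
        )
        draws[d] = _stat(score_cohort(cohort, rand_sig, min_coverage=min_coverage))
    return NullDistribution(draws=draws, observed=observed, seed=seed, statistic=statistic)
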