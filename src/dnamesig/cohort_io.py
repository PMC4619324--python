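"""Data model and tabular I/O for methylation-cohort analyses.

The central objects are a probe-by-sample matrix of beta values (methylation
fractions in [0, 1] from Infinium-style arrays), per-sample clinical
annotation (binary marker status, treatment arm, survival time and event),
and their pairing into a :class:`Cohort`.

Files are plain TSV, UTF-8, with ``NA`` or an empty cell for missing values —
the dialect most methylation-array exports use.  Beta values are validated,
never clipped: a value outside [0, 1] is an upstream error worth surfacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
TREATMENTS = ("carboplatin", "cisplatin", "none")
MARKER_STATUSES = ("positive", "negative", "unknown")

#: tolerance for floating-point round-off when validating the [0, 1] range
BETA_RANGE_TOL = 1e-9


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class CpGAnnotation:
    """Annotation of a single array probe.

    Parameters
    ----------
    probe_id
        Array probe identifier (e.g. ``cg00000029``).
    gene_symbols
        Gene symbols the probe maps to; may be empty.
    platform_flags
        Non-empty subset of ``{"27k", "450k"}``.
    """

    probe_id: str
    gene_symbols: tuple[str, ...] = ()
    platform_flags: frozenset[str] = frozenset({"27k"})

    def __post_init__(self) -> None:
        if not self.platform_flags:
            raise ValidationError(f"probe {self.probe_id}: platform_flags must be non-empty")


@dataclass
class BetaMatrix:
    """Probe-by-sample grid of beta values.

    ``values`` is a float array of shape ``(n_probes, n_samples)``; missing
    entries are NaN.  All non-missing entries lie in [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {name} ids: {dupes[:5]}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -BETA_RANGE_TOL or finite.max() > 1 + BETA_RANGE_TOL):
            bad = np.argwhere(
                np.isfinite(self.values)
                & ((self.values < -BETA_RANGE_TOL) | (self.values > 1 + BETA_RANGE_TOL))
            )[0]
            raise ValidationError(
                f"beta value {self.values[bad[0], bad[1]]} out of [0, 1] at "
                f"probe {self.probe_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, idx])

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        pos = {p: i for i, p in enumerate(self.probe_ids)}
        idx = [pos[p] for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[idx, :])


@dataclass(frozen=True)
class SampleAnnotation:
    """Clinical annotation for one sample.

    ``marker_status`` is the binary phenotype the signature surrogates
    (e.g. lncRNA expression positive/negative by qPCR); ``treatment`` is the
    platinum arm; ``time`` is survival time in years with ``event`` the death
    indicator.  Covariates may be missing (``None``).
    """

    sample_id: str
    marker_status: str = "unknown"
    treatment: str = "none"
    time: float | None = None
    event: int | None = None
    age: float | None = None
    stage: str | None = None
    grade: str | None = None
    residual: str | None = None

    def __post_init__(self) -> None:
        if self.marker_status not in MARKER_STATUSES:
            raise ValidationError(
                f"sample {self.sample_id}: marker_status {self.marker_status!r} "
                f"not in {MARKER_STATUSES}"
            )
        if self.treatment not in TREATMENTS:
            raise FormatError(
                f"sample {self.sample_id}: treatment {self.treatment!r} not in {TREATMENTS}"
            )
        if self.time is not None and not self.time > 0:
            raise ValidationError(f"sample {self.sample_id}: time must be > 0, got {self.time}")
        if self.event is not None and self.event not in (0, 1):
            raise ValidationError(f"sample {self.sample_id}: event must be 0/1, got {self.event}")


@dataclass
class Cohort:
    """A beta matrix paired with sample annotations in identical order."""

    beta: BetaMatrix
    samples: list[SampleAnnotation]
    name: str = "cohort"

    def __post_init__(self) -> None:
        if [s.sample_id for s in self.samples] != self.beta.sample_ids:
            raise ValidationError(
                f"cohort {self.name}: sample annotation order does not match beta matrix"
            )

    @property
    def n_samples(self) -> int:
        return self.beta.n_samples

    def clinical_frame(self) -> pd.DataFrame:
        """Sample annotations as a DataFrame indexed by sample_id."""
        rows = [
            {
                "sample_id": s.sample_id,
                "marker_status": s.marker_status,
                "treatment": s.treatment,
                "time": s.time,
                "event": s.event,
                "age": s.age,
                "stage": s.stage,
                "grade": s.grade,
                "residual": s.residual,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def marker_mask(self) -> np.ndarray:
        """Boolean array, True where marker_status == 'positive'."""
        return np.array([s.marker_status == "positive" for s in self.samples])

    def subset(self, sample_ids: Sequence[str], name: str | None = None) -> "Cohort":
        wanted = set(sample_ids)
        keep = [s for s in self.samples if s.sample_id in wanted]
        ids = [s.sample_id for s in keep]
        return Cohort(self.beta.subset_samples(ids), keep, name or self.name)


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(
    path: str | Path, probe_orientation: Literal["rows", "columns"] = "rows"
) -> BetaMatrix:
    """Read a TSV beta matrix (probes as rows by default).

    The first column holds probe ids and the header row sample ids; pass
    ``probe_orientation="columns"`` for transposed files.  Empty cells and
    ``NA`` become missing.  Values outside [0, 1] (beyond 1e-9 round-off) and
    non-numeric cells raise with the offending coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_TOKEN, ""], keep_default_na=False,
        dtype=str,
    )
    if probe_orientation == "columns":
        frame = frame.T
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path.name}: non-numeric value {frame.iat[r, c]!r} at "
            f"probe {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    try:
        return BetaMatrix.from_frame(numeric.astype(float))
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path.name}: {exc}") from None


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write a beta matrix as TSV, probes as rows, missing as ``NA``."""
    matrix.to_frame().to_csv(Path(path), sep="\t", na_rep=MISSING_TOKEN, index_label="probe_id")


_SHEET_REQUIRED = ("sample_id", "marker_status", "treatment", "time", "event")
_SHEET_COVARIATES = ("age", "stage", "grade", "residual")


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Read a TSV sample sheet into annotations.

    Mandatory columns: sample_id, marker_status, treatment, time, event.
    Optional covariates: age, stage, grade, residual.  Closed vocabularies
    are enforced; missing covariates stay missing.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False, dtype=str
    )
    missing_cols = [c for c in _SHEET_REQUIRED if c not in frame.columns]
    if missing_cols:
        raise FormatError(f"{path.name}: missing mandatory columns {missing_cols}")
    out: list[SampleAnnotation] = []
    for _, row in frame.iterrows():
        def _opt(col: str) -> str | None:
            v = row.get(col)
            return None if v is None or pd.isna(v) else str(v)

        time = _opt("time")
        event = _opt("event")
        age = _opt("age")
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                marker_status=_opt("marker_status") or "unknown",
                treatment=_opt("treatment") or "none",
                time=float(time) if time is not None else None,
                event=int(float(event)) if event is not None else None,
                age=float(age) if age is not None else None,
                stage=_opt("stage"),
                grade=_opt("grade"),
                residual=_opt("residual"),
            )
        )
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path.name}: duplicate sample ids")
    return out


def write_sample_sheet(samples: Iterable[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "marker_status": s.marker_status,
                "treatment": s.treatment,
                "time": s.time,
                "event": s.event,
                "age": s.age,
                "stage": s.stage,
                "grade": s.grade,
                "residual": s.residual,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", na_rep=MISSING_TOKEN, index=False)


def read_probe_annotation(path: str | Path) -> dict[str, CpGAnnotation]:
    """Read probe annotation TSV (probe_id, gene_symbols ;-joined, platforms)."""
    frame = pd.read_csv(
        Path(path), sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False, dtype=str
    )
    out: dict[str, CpGAnnotation] = {}
    for _, row in frame.iterrows():
        pid = str(row["probe_id"])
        if pid in out:
            raise FormatError(f"duplicate probe id {pid!r} in annotation")
        genes = row.get("gene_symbols")
        platforms = row.get("platforms")
        out[pid] = CpGAnnotation(
            probe_id=pid,
            gene_symbols=tuple(g for g in str(genes).split(";") if g) if pd.notna(genes) else (),
            platform_flags=frozenset(str(platforms).split(";"))
            if pd.notna(platforms)
            else frozenset({"27k"}),
        )
    return out


def assemble_cohort(
    beta: BetaMatrix,
    samples: Sequence[SampleAnnotation],
    on_mismatch: Literal["intersect", "strict"] = "strict",
    name: str = "cohort",
) -> Cohort:
    """Pair a beta matrix with sample annotations.

    ``strict`` requires identical id sets; ``intersect`` subsets both sides to
    the shared ids, keeping the beta-matrix sample order (deterministic).
    """
    by_id = {s.sample_id: s for s in samples}
    shared = [sid for sid in beta.sample_ids if sid in by_id]
    if not shared:
        raise ValidationError("no shared sample ids between beta matrix and sample sheet")
    if on_mismatch == "strict":
        if set(by_id) != set(beta.sample_ids):
            only_beta = sorted(set(beta.sample_ids) - set(by_id))
            only_sheet = sorted(set(by_id) - set(beta.sample_ids))
            raise ValidationError(
                f"sample id mismatch (strict): {len(only_beta)} only in beta "
                f"{only_beta[:3]}, {len(only_sheet)} only in sheet {only_sheet[:3]}"
            )
        ordered = [by_id[sid] for sid in beta.sample_ids]
        return Cohort(beta, ordered, name)
    logger.info(
        "assemble_cohort(intersect): %d shared of %d beta / %d sheet samples",
        len(shared), beta.n_samples, len(samples),
    )
    return Cohort(beta.subset_samples(shared), [by_id[sid] for sid in shared], name)
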