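"""File formats and in-memory containers for paired tumor/normal cohorts.

Expression matrices are tab-separated text with gene ids in the first
column and sample ids in the header.  A pairing table links each patient
to one tumor and one normal sample; survival and clinical tables are
keyed by patient.  Gene sets use the standard GMT format.

All downstream analysis consumes one of seven *feature views* of a
paired cohort: the tumor matrix, the normal matrix, the per-patient
tumor-minus-normal log fold change, or a column-concatenation of two or
three of these (each block standardized feature-wise before joining so
no block dominates a penalized fit purely by scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VIEW_LABELS = (
    "tumor",
    "normal",
    "foldchange",
    "tumor+normal",
    "tumor+foldchange",
    "normal+foldchange",
    "tumor+normal+foldchange",
)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class PairingError(ValueError):
    """A tumor/normal pairing table is inconsistent with the expression data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix, log2 scale by convention.

    ``df`` is indexed by gene id with sample ids as columns.  Gene and
    sample ids must be unique and all values finite.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.df.columns.has_duplicates:
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise FormatError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.df.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.df.loc[:, list(sample_ids)])


@dataclass
class PairedCohort:
    """Tumor and normal expression over the same ordered patients.

    Both matrices share an identical gene index; column ``j`` of each
    matrix belongs to patient ``patient_ids[j]`` through ``pairing``.
    """

    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    patient_ids: list[str]
    pairing: dict[str, tuple[str, str]]  # patient -> (tumor sample, normal sample)

    def __post_init__(self) -> None:
        if self.tumor.gene_ids != self.normal.gene_ids:
            raise PairingError("tumor and normal views must share identical gene ids")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise PairingError("duplicate patient ids")
        n = len(self.patient_ids)
        if self.tumor.shape[1] != n or self.normal.shape[1] != n:
            raise PairingError("per-view sample count must equal patient count")
        for j, pid in enumerate(self.patient_ids):
            t_id, n_id = self.pairing[pid]
            if self.tumor.sample_ids[j] != t_id or self.normal.sample_ids[j] != n_id:
                raise PairingError(f"column order does not follow pairing at patient {pid!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.tumor.gene_ids

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class SurvivalTable:
    """Right-censored follow-up per patient: time (days) and event indicator."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids in survival table")
        if self.time.shape != (len(self.patient_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event length must match patient count")
        if not np.isfinite(self.time).all() or (self.time < 0).any():
            raise ValueError("survival times must be finite and nonnegative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def reorder(self, patient_ids: Sequence[str]) -> "SurvivalTable":
        idx = {p: i for i, p in enumerate(self.patient_ids)}
        pos = [idx[p] for p in patient_ids]
        return SurvivalTable(list(patient_ids), self.time[pos], self.event[pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "time": self.time, "event": self.event}
        )


@dataclass
class ClinicalTable:
    """Named categorical groupings per patient; missing labels are NaN."""

    df: pd.DataFrame  # patients x features, index = patient ids

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate patient ids in clinical table")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def labels(self, feature: str) -> pd.Series:
        return self.df[feature]


@dataclass
class FeatureView:
    """Patients x features design matrix for one of the seven view labels."""

    label: str
    patient_ids: list[str]
    feature_names: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("feature view shape inconsistent with id lists")
        if not np.isfinite(self.X).all():
            raise ValueError("feature view must be finite")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, log2_counts: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV; first column gene id, header sample ids.

    With ``log2_counts=True`` raw nonnegative counts are transformed
    log2(x + 1) at load time so every platform enters the pipeline on a
    log scale and the fold-change view is an additive log ratio.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if len(line.rstrip("\n").split("\t")) != width:
                raise FormatError(f"{path.name}:{lineno}: ragged row")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path.name}: non-numeric expression cell ({exc})") from exc
    if log2_counts:
        if (df.to_numpy() < 0).any():
            raise FormatError("log2_counts requires nonnegative values")
        df = np.log2(df + 1.0)
    # canonical gene order so all views align deterministically
    df = df.sort_index(kind="stable")
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    # %.17g keeps the write -> read round trip value-exact for doubles
    expr.df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_pairing(path: str | Path) -> pd.DataFrame:
    """Read a pairing TSV: tumor_id, normal_id, optional patient_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError("pairing table needs tumor_id and normal_id columns")
    if "tumor_id" not in cols or "normal_id" not in cols:
        df.columns = ["tumor_id", "normal_id"] + cols[2:]
    if "patient_id" not in df.columns:
        df["patient_id"] = [f"P{i:04d}" for i in range(len(df))]
    return df[["tumor_id", "normal_id", "patient_id"]]


def build_paired_cohort(expr: ExpressionMatrix, pairing: pd.DataFrame) -> PairedCohort:
    """Split one expression matrix into aligned tumor and normal views.

    Samples absent from the pairing table are dropped (count logged);
    a sample referenced twice or missing from the matrix is an error.
    """
    pairing = pairing.reset_index(drop=True)
    used: list[str] = []
    for col in ("tumor_id", "normal_id"):
        used.extend(pairing[col].tolist())
    seen: set[str] = set()
    for sid in used:
        if sid in seen:
            raise PairingError(f"sample {sid!r} referenced more than once in pairing")
        seen.add(sid)
    missing = [sid for sid in used if sid not in expr.df.columns]
    if missing:
        raise PairingError(f"pairing references absent samples: {missing[:5]}")
    if pairing["patient_id"].duplicated().any():
        raise PairingError("duplicate patient ids in pairing table")

    n_drop = expr.shape[1] - len(used)
    if n_drop > 0:
        logger.info("dropping %d unpaired samples", n_drop)

    patient_ids = pairing["patient_id"].tolist()
    tumor = expr.subset_samples(pairing["tumor_id"].tolist())
    normal = expr.subset_samples(pairing["normal_id"].tolist())
    mapping = {
        row.patient_id: (row.tumor_id, row.normal_id) for row in pairing.itertuples()
    }
    return PairedCohort(tumor=tumor, normal=normal, patient_ids=patient_ids, pairing=mapping)


def compute_fold_change(cohort: PairedCohort) -> ExpressionMatrix:
    """Per-gene, per-patient tumor minus normal log expression (log2 ratio)."""
    fc = pd.DataFrame(
        cohort.tumor.values - cohort.normal.values,
        index=cohort.tumor.df.index,
        columns=cohort.patient_ids,
    )
    return ExpressionMatrix(fc)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def make_feature_view(cohort: PairedCohort, label: str) -> FeatureView:
    """Build a patients x genes design matrix for one of the seven labels.

    Single views are the transposed matrices as-is; concatenated views
    standardize each block feature-wise (mean 0, sd 1) before joining.
    """
    if label not in VIEW_LABELS:
        raise ValueError(f"unknown view label {label!r}; expected one of {VIEW_LABELS}")
    parts = label.split("+")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    fc = compute_fold_change(cohort) if "foldchange" in parts else None
    for part in parts:
        if part == "tumor":
            mat = cohort.tumor.values.T
        elif part == "normal":
            mat = cohort.normal.values.T
        else:
            mat = fc.values.T  # type: ignore[union-attr]
        if len(parts) > 1:
            mat = _standardize(mat)
        blocks.append(mat)
        names.extend(f"{part}:{g}" for g in cohort.gene_ids)
    X = np.hstack(blocks)
    return FeatureView(label=label, patient_ids=list(cohort.patient_ids),
                       feature_names=names, X=X)


def expression_view(cohort: PairedCohort, label: str) -> ExpressionMatrix:
    """The genes x patients matrix behind a single-compartment label."""
    if label == "tumor":
        df = pd.DataFrame(cohort.tumor.values, index=cohort.tumor.df.index,
                          columns=cohort.patient_ids)
        return ExpressionMatrix(df)
    if label == "normal":
        df = pd.DataFrame(cohort.normal.values, index=cohort.normal.df.index,
                          columns=cohort.patient_ids)
        return ExpressionMatrix(df)
    if label == "foldchange":
        return compute_fold_change(cohort)
    raise ValueError(f"not a single-compartment label: {label!r}")


def read_survival_table(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"survival table missing column {col!r}")
    return SurvivalTable(df["patient_id"].tolist(),
                         df["time"].to_numpy(float),
                         df["event"].to_numpy(int))


def write_survival_table(surv: SurvivalTable, path: str | Path) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("patient_id")
    return ClinicalTable(df)


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    clin.df.to_csv(path, sep="\t", index_label="patient_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name <tab> description <tab> members...

    Duplicate members are dropped (first occurrence kept); blank lines
    are skipped with a log entry; a line with fewer than three columns
    or an empty member list is a format error.
    """
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                logger.info("%s:%d: skipping blank line", path.name, lineno)
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: GMT line with <3 columns")
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise FormatError(f"{path.name}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_mutation_matrix(path: str | Path) -> pd.DataFrame:
    """Binary genes x patients somatic-mutation indicator matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise FormatError("mutation matrix must be binary")
    return df.astype(int)
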