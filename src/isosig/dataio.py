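"""Domain types, file readers/writers, and clinical-label handling.

All tabular data is tab-separated UTF-8 with ``.`` as the decimal mark.
Missing values are written as the single reserved token ``NA`` and held
in memory as ``None`` (labels) or ``NaN`` (numerics); empty strings are
never silently coerced.

Coordinates follow the GTF convention: 1-based, inclusive at both ends.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Reserved missing-value token in all tabular files.
MISSING = "NA"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Exon structure of a single transcript.

    Exons are 1-based inclusive ``(start, end)`` genomic intervals, sorted
    and non-overlapping.  Internal exon boundaries define the splice sites:
    each exon end except the last is a donor, each exon start except the
    first is an acceptor.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has zero exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: exon start {s} >= end {e}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons at {e0}/{s1}")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def splice_sites(self) -> frozenset[int]:
        """Internal exon boundary coordinates (donors and acceptors)."""
        sites: set[int] = set()
        for (_, end), (start, _) in zip(self.exons, self.exons[1:]):
            sites.add(end)
            sites.add(start)
        return frozenset(sites)


@dataclass(frozen=True)
class ComparisonDesign:
    """Two disjoint named sample groups (early vs late) for one stage class."""

    class_name: str
    group_early: tuple[str, ...]
    group_late: tuple[str, ...]
    tumor_type_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        early = tuple(sorted(set(self.group_early)))
        late = tuple(sorted(set(self.group_late)))
        if not early or not late:
            raise ValueError(f"design {self.class_name}: both groups must be non-empty")
        if set(early) & set(late):
            raise ValueError(f"design {self.class_name}: groups overlap")
        object.__setattr__(self, "group_early", early)
        object.__setattr__(self, "group_late", late)

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group_early + self.group_late

    def labels(self) -> pd.Series:
        """Binary label vector: 0 = early, 1 = late, indexed by sample."""
        return pd.Series(
            [0] * len(self.group_early) + [1] * len(self.group_late),
            index=list(self.samples),
            name=self.class_name,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. the 50 cancer-hallmark collections."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, *, allow_missing: bool = False) -> pd.DataFrame:
    """Read a features × samples abundance matrix from TSV.

    First column holds feature ids, the header row sample ids.  Values must
    be non-negative reals; ``NA`` is accepted only when *allow_missing* is
    set (PSI matrices carry missingness, TPM matrices do not).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], keep_default_na=False, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:5]}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc
    if not allow_missing and values.isna().any().any():
        feat, samp = _first_offender(values.isna())
        raise ParseError(f"{path}: missing value at feature {feat!r}, sample {samp!r}")
    neg = values < 0
    if neg.any().any():
        feat, samp = _first_offender(neg)
        raise ParseError(f"{path}: negative value at feature {feat!r}, sample {samp!r}")
    return values


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    feat, samp = stacked[stacked].index[0]
    return str(feat), str(samp)


def write_matrix(matrix: pd.DataFrame, path: str | Path, *, header_lines: Sequence[str] = ()) -> None:
    """Write a matrix in the same TSV dialect ``read_matrix`` consumes."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", na_rep=MISSING, index_label="feature_id")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptAnnotation]:
    """Parse exon features from a GTF file into transcript annotations.

    Only ``exon`` rows are consumed; each must carry a ``transcript_id``
    attribute.  Exons may appear in any order.  A malformed line raises
    :class:`ParseError` naming the line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str | None]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from exc
            attr_map = dict(_ATTR_RE.findall(attrs))
            tid = attr_map.get("transcript_id")
            if not tid:
                raise ParseError(f"{path}:{lineno}: exon without transcript_id attribute")
            if tid in meta and (meta[tid][0] != chrom or meta[tid][1] != strand):
                raise ParseError(f"{path}:{lineno}: transcript {tid!r} spans chrom/strand combinations")
            meta.setdefault(tid, (chrom, strand, attr_map.get("gene_id")))
            exons.setdefault(tid, []).append((start, end))
    annotations = []
    for tid, (chrom, strand, gene_id) in meta.items():
        try:
            annotations.append(
                TranscriptAnnotation(tid, chrom, strand, tuple(exons[tid]), gene_id=gene_id)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: transcript {tid!r}: {exc}") from exc
    return annotations


def write_gtf(annotations: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ann in annotations:
            gid = ann.gene_id or ann.transcript_id
            for i, (start, end) in enumerate(ann.exons, start=1):
                attrs = f'gene_id "{gid}"; transcript_id "{ann.transcript_id}"; exon_number "{i}";'
                fh.write(
                    f"{ann.chrom}\tisosig\texon\t{start}\t{end}\t.\t{ann.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id",
    "tumor_type",
    "stage_T",
    "stage_N",
    "stage_M",
    "stage_S",
    "survival_days",
    "event",
]

_EVENTS = {"deceased", "censored"}


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical table (tab-separated, documented header).

    Survival is taken from ``survival_days`` when present; otherwise it is
    derived from ISO-8601 ``collection_date`` plus ``death_date`` (deceased)
    or ``last_contact_date`` (censored).  Duplicate sample rows are rejected
    rather than reconciled.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing_cols = {"sample_id", "tumor_type", "event"} - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {sorted(missing_cols)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:5]}")
    df = df.set_index("sample_id")

    if "survival_days" in df.columns and df["survival_days"].notna().any():
        surv = pd.to_numeric(df["survival_days"], errors="raise")
    else:
        surv = _survival_from_dates(df, path)
    if (surv.dropna() < 0).any():
        bad = surv[surv < 0].index.tolist()
        raise ParseError(f"{path}: negative survival for samples {bad[:5]}")

    out = pd.DataFrame(index=df.index)
    out["tumor_type"] = df["tumor_type"]
    for cls in "TNMS":
        col = f"stage_{cls}"
        raw = df[col] if col in df.columns else pd.Series(pd.NA, index=df.index, dtype=object)
        out[col] = raw.map(lambda v: normalize_stage(v) if pd.notna(v) else None)
    event = df["event"].str.lower()
    bad_events = set(event.dropna()) - _EVENTS
    if bad_events:
        raise ParseError(f"{path}: unknown event labels {sorted(bad_events)}")
    out["survival_days"] = surv.astype(float)
    out["event"] = event == "deceased"
    if (out["event"] & out["survival_days"].isna()).any():
        bad = out.index[out["event"] & out["survival_days"].isna()].tolist()
        raise ParseError(f"{path}: deceased samples without survival information {bad[:5]}")
    return out


def _survival_from_dates(df: pd.DataFrame, path: str | Path) -> pd.Series:
    for col in ("collection_date", "death_date", "last_contact_date"):
        if col not in df.columns:
            raise ParseError(f"{path}: need survival_days or date columns; {col!r} absent")
    collect = pd.to_datetime(df["collection_date"], format="%Y-%m-%d")
    death = pd.to_datetime(df["death_date"], format="%Y-%m-%d", errors="coerce")
    contact = pd.to_datetime(df["last_contact_date"], format="%Y-%m-%d", errors="coerce")
    deceased = df["event"].str.lower() == "deceased"
    end = death.where(deceased, contact)
    return (end - collect).dt.days.astype(float)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out["event"] = np.where(out["event"], "deceased", "censored")
    out.to_csv(path, sep="\t", na_rep=MISSING, index_label="sample_id")


# ---------------------------------------------------------------------------
# Stage-label normalization
# ---------------------------------------------------------------------------

_ROMAN = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4}
_TNMS_RE = re.compile(r"^([TNMS])\s*([0-9])[A-C]?$", re.IGNORECASE)
_STAGE_RE = re.compile(r"^STAGE\s*(0|IV|III|II|I)[A-C]?$", re.IGNORECASE)


def normalize_stage(raw_label: str | None) -> str | None:
    """Collapse sub-divided TNM/S labels to their common class.

    ``T1a``/``T1b``/``T1c`` all map to ``T1``; ``Stage IIIB`` maps to
    ``S3``.  Unknown, unevaluable (``TX``) or empty labels map to missing
    (``None``) and are logged.  The mapping is idempotent.
    """
    if raw_label is None or (isinstance(raw_label, float) and np.isnan(raw_label)):
        return None
    label = str(raw_label).strip()
    if not label or label.upper() == MISSING:
        return None
    m = _TNMS_RE.match(label)
    if m:
        return f"{m.group(1).upper()}{m.group(2)}"
    m = _STAGE_RE.match(label)
    if m:
        return f"S{_ROMAN[m.group(1).upper()]}"
    logger.info("unrecognized stage label %r mapped to missing", raw_label)
    return None


# ---------------------------------------------------------------------------
# Comparison design
# ---------------------------------------------------------------------------


def build_design(
    clinical: pd.DataFrame,
    class_name: str,
    early_labels: Iterable[str],
    late_labels: Iterable[str],
    *,
    tumor_types: Iterable[str] | None = None,
) -> ComparisonDesign:
    """Assemble the early/late comparison for one stage class.

    Samples with a missing label for *class_name* are excluded — only
    patients with a defined stage enter the predictive models.  *tumor_types*
    optionally restricts the cohort (and enables pooled per-type balanced
    subsampling downstream).
    """
    early_labels = set(early_labels)
    late_labels = set(late_labels)
    if early_labels & late_labels:
        raise ValueError(f"early and late label sets overlap: {sorted(early_labels & late_labels)}")
    col = f"stage_{class_name}" if class_name in set("TNMS") else class_name
    if col not in clinical.columns:
        raise ValueError(f"clinical table lacks column {col!r}")
    table = clinical
    if tumor_types is not None:
        table = table[table["tumor_type"].isin(set(tumor_types))]
    labels = table[col]
    early = table.index[labels.isin(early_labels)].tolist()
    late = table.index[labels.isin(late_labels)].tolist()
    return ComparisonDesign(
        class_name=class_name,
        group_early=tuple(early),
        group_late=tuple(late),
        tumor_type_of=table["tumor_type"].to_dict(),
    )


def load_stage_groups(path: str | Path | None = None) -> dict:
    """Load the per-tumor-type early/late stage-label configuration.

    The packaged default covers 12 TCGA tumor types: earliest vs latest
    available stage per type and class, with adjacent stages merged where
    a single stage is rare; users override it with their own YAML file.
    """
    if path is None:
        ref = _importlib_resources.files("isosig") / "resources" / "stage_groups.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated symbols)."""
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)
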