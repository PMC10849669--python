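"""Mutational catalogs: the samples × channels count matrix and its statistics.

A catalog holds nonnegative integer mutation counts for a set of samples over
a fixed channel schema, plus optional per-sample metadata (cancer type, study,
...).  This module provides CSV and portal-style JSON readers, a CSV writer,
per-sample spectra, summary tables, two-sample spectrum comparison, and
grouped log-count boxplot statistics — the plot-ready tables behind the usual
catalog-exploration figures.

Two CSV layouts are understood:

* wide — header ``sample,<label1>,...,<labelN>``, one row per sample;
* long — header ``sample,mutationType,mutations``, one row per observed
  (sample, channel) pair; absent channels are implicitly zero.

The JSON dialect mirrors a portal API payload: an array of records with
fields ``sample``, ``profile`` (schema family, e.g. ``"SBS"``), ``matrix``
(channel count, e.g. ``96``), ``mutationType`` and ``mutations``.  The field
names are an emulation of such payloads, not a published contract.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import ChannelSchema
from .errors import SampleLookupError, SchemaMismatchError, ValidationError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("sample", "mutationType", "mutations")


@dataclass
class MutationalCatalog:
    """Integer mutation-count matrix, samples × channels.

    Parameters
    ----------
    schema
        Channel schema; columns of ``counts`` follow ``schema.channels``.
    sample_ids
        Ordered, unique sample identifiers (rows of ``counts``).
    counts
        ``(n_samples, n_channels)`` array of nonnegative integers.
    metadata
        Optional per-sample string key → value mapping, keyed by sample id
        (e.g. ``{"SP1": {"cancer_type": "Lung-AdenoCA"}}``).
    """

    schema: ChannelSchema
    sample_ids: list[str]
    counts: np.ndarray
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.sample_ids), len(self.schema)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.schema)} channels"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integral")
            arr = np.round(arr)
        arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"channel {self.schema.channels[j]!r}"
            )
        self.counts = arr
        unknown = set(self.metadata) - set(self.sample_ids)
        if unknown:
            raise ValidationError(f"metadata for unknown samples: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self._row_index(sample_id)]

    def _row_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise SampleLookupError(
                f"unknown sample {sample_id!r}; available: {self.sample_ids}"
            ) from None

    def totals(self) -> np.ndarray:
        """Per-sample total mutation counts, in catalog order."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (index = sample ids, columns = channels)."""
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=list(self.schema.channels)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationalCatalog):
            return NotImplemented
        return (
            self.schema == other.schema
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class Spectrum:
    """A per-channel mutation fraction vector (sums to 1, or all zero)."""

    schema: ChannelSchema
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.schema),):
            raise ValidationError(
                f"spectrum length {v.shape} does not match schema ({len(self.schema)})"
            )
        if v.size and v.min() < 0:
            raise ValidationError("spectrum values must be nonnegative")
        total = v.sum()
        if total != 0 and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"spectrum sums to {total}, expected 1 or 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey boxplot statistics for one group of (transformed) totals."""

    group: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValidationError("quartiles out of order")
        if self.whisker_low > self.q1 or self.whisker_high < self.q3:
            raise ValidationError("whiskers inside the quartile box")


# ---------------------------------------------------------------------------
# I/O


def _catalog_from_long(
    frame: pd.DataFrame, schema: ChannelSchema, source: str
) -> MutationalCatalog:
    sample_order: list[str] = []
    seen: set[str] = set()
    for s in frame["sample"].astype(str):
        if s not in seen:
            seen.add(s)
            sample_order.append(s)
    counts = np.zeros((len(sample_order), len(schema)), dtype=np.int64)
    row_of = {s: i for i, s in enumerate(sample_order)}
    for pos, (s, label, count) in enumerate(
        zip(frame["sample"].astype(str), frame["mutationType"], frame["mutations"])
    ):
        j = schema.index_of(str(label))
        c = _as_count(count, f"{source}, record {pos}")
        counts[row_of[s], j] += c
    return MutationalCatalog(schema, sample_order, counts)


def _as_count(value: object, where: str) -> int:
    try:
        f = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric count {value!r} ({where})") from None
    if not np.isfinite(f) or f != round(f):
        raise ValidationError(f"non-integer count {value!r} ({where})")
    if f < 0:
        raise ValidationError(f"negative count {value!r} ({where})")
    return int(round(f))


def read_catalog_csv(path, schema: ChannelSchema) -> MutationalCatalog:
    """Read a catalog from CSV, auto-detecting wide vs long layout.

    Channel columns are reordered into schema order regardless of file order;
    channels absent from a long-layout file are filled with zeros.
    """
    frame = pd.read_csv(path, dtype=str)
    cols = list(frame.columns)
    if cols[:3] == list(LONG_COLUMNS) and len(cols) == 3:
        return _catalog_from_long(frame, schema, str(path))
    if not cols or cols[0] != "sample":
        raise ValidationError(
            f"{path}: first CSV column must be 'sample' (wide) or the header "
            f"must be {','.join(LONG_COLUMNS)} (long); got {cols[:3]}"
        )
    channel_cols = cols[1:]
    for label in channel_cols:
        if label not in schema:
            raise SchemaMismatchError(
                f"{path}: unknown channel label {label!r} for schema {schema.name}"
            )
    samples = frame["sample"].astype(str).tolist()
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids {dupes}")
    counts = np.zeros((len(samples), len(schema)), dtype=np.int64)
    for label in channel_cols:
        j = schema.index_of(label)
        col = frame[label]
        for i, v in enumerate(col):
            counts[i, j] = _as_count(v, f"{path}, row {i + 2}")  # 1 header + 1-based
    return MutationalCatalog(schema, samples, counts)


def write_catalog_csv(catalog: MutationalCatalog, path) -> None:
    """Write a catalog as wide-layout CSV (``sample`` + channels in schema order)."""
    frame = catalog.to_frame().reset_index(names="sample")
    frame.to_csv(path, index=False, lineterminator="\n")


_PROFILE_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def _schema_family(schema: ChannelSchema) -> tuple[str, int]:
    """Split a schema name like ``SBS96`` into (``"SBS"``, 96)."""
    m = _PROFILE_RE.match(schema.name)
    if m:
        return m.group(1), len(schema)
    return schema.name, len(schema)


def parse_portal_json(payload: str, schema: ChannelSchema) -> MutationalCatalog:
    """Parse a portal-style JSON payload into a catalog.

    The result is identical to reading the equivalent long CSV; channels not
    mentioned for a sample are zero.  Records whose ``profile``/``matrix``
    disagree with the requested schema are rejected.
    """
    try:
        records = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON payload: {exc}") from exc
    if not isinstance(records, list):
        raise ValidationError("payload must be a JSON array of records")
    if not records:
        raise ValidationError("no records in payload")
    family, n_channels = _schema_family(schema)
    rows = {"sample": [], "mutationType": [], "mutations": []}
    for i, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise ValidationError(f"record {i} is not an object")
        for key in ("sample", "profile", "matrix", "mutationType", "mutations"):
            if key not in rec:
                raise ValidationError(f"record {i} missing required field {key!r}")
        if str(rec["profile"]) != family or int(rec["matrix"]) != n_channels:
            raise SchemaMismatchError(
                f"record {i}: profile/matrix "
                f"({rec['profile']}, {rec['matrix']}) does not match requested "
                f"schema {schema.name} ({family}, {n_channels})"
            )
        rows["sample"].append(str(rec["sample"]))
        rows["mutationType"].append(str(rec["mutationType"]))
        rows["mutations"].append(rec["mutations"])
    return _catalog_from_long(pd.DataFrame(rows), schema, "payload")


# ---------------------------------------------------------------------------
# Statistics


def to_spectrum(catalog: MutationalCatalog, sample_id: str) -> Spectrum:
    """Normalize one sample's counts to fractions (all-zero for empty samples)."""
    row = catalog.row(sample_id).astype(float)
    total = row.sum()
    values = row / total if total > 0 else np.zeros_like(row)
    return Spectrum(catalog.schema, values)


def sample_summary(catalog: MutationalCatalog) -> pd.DataFrame:
    """Per-sample totals and per-substitution-class subtotals.

    Returns one row per sample in catalog order with columns
    ``sample``, ``total_mutations`` and one column per substitution class
    (e.g. ``C>A`` ... ``T>G``); class subtotals sum to the total.
    """
    classes = catalog.schema.substitution_classes
    class_of = np.array(
        [classes.index(catalog.schema.substitution_of(c)) for c in catalog.schema.channels]
    )
    data = {"sample": catalog.sample_ids, "total_mutations": catalog.totals()}
    for k, cls in enumerate(classes):
        data[cls] = catalog.counts[:, class_of == k].sum(axis=1)
    return pd.DataFrame(data)


@dataclass(frozen=True)
class SpectraComparison:
    """Channel-wise comparison of two sample spectra."""

    table: pd.DataFrame  # columns: channel, <a>, <b>, difference
    cosine_similarity: float
    rss: float


def compare_spectra(
    catalog: MutationalCatalog, sample_a: str, sample_b: str
) -> SpectraComparison:
    """Compare two samples' spectra channel by channel.

    ``difference`` is spectrum(a) − spectrum(b); ``rss`` is the sum of squared
    differences and ``cosine_similarity`` the cosine of the two spectra.
    """
    from .similarity import cosine_similarity

    spec_a = to_spectrum(catalog, sample_a).values
    spec_b = to_spectrum(catalog, sample_b).values
    table = pd.DataFrame(
        {
            "channel": list(catalog.schema.channels),
            sample_a: spec_a,
            sample_b if sample_b != sample_a else f"{sample_b} (b)": spec_b,
            "difference": spec_a - spec_b,
        }
    )
    cos = cosine_similarity(spec_a, spec_b)
    rss = float(np.sum((spec_a - spec_b) ** 2))
    return SpectraComparison(table, cos, rss)


def grouped_log_boxplot(
    catalog: MutationalCatalog, group_key: str
) -> list[BoxplotStats]:
    """Tukey boxplot statistics of log10 total mutation counts per group.

    Samples are grouped by the metadata value under ``group_key``; totals are
    log10-transformed, quartiles use linear interpolation between order
    statistics, and whiskers extend to the most extreme data point within
    1.5×IQR of the quartile box.  Zero-total samples cannot be log-transformed
    and are excluded with a warning.
    """
    missing = [s for s in catalog.sample_ids if group_key not in catalog.metadata.get(s, {})]
    if missing:
        raise ValidationError(
            f"samples missing metadata key {group_key!r}: {missing}"
        )
    totals = catalog.totals()
    groups: dict[str, list[float]] = {}
    excluded: list[str] = []
    for s, t in zip(catalog.sample_ids, totals):
        if t <= 0:
            excluded.append(s)
            continue
        groups.setdefault(catalog.metadata[s][group_key], []).append(np.log10(float(t)))
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} zero-total sample(s) from log boxplot: {excluded}",
            stacklevel=2,
        )
    out: list[BoxplotStats] = []
    for group in sorted(groups):
        vals = np.sort(np.asarray(groups[group]))
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        # clamp to the box when every point on one side is an outlier
        whisker_low = min(float(inside.min()), float(q1)) if inside.size else float(q1)
        whisker_high = max(float(inside.max()), float(q3)) if inside.size else float(q3)
        outliers = tuple(float(v) for v in vals if v < whisker_low or v > whisker_high)
        out.append(
            BoxplotStats(
                group=group,
                n=len(vals),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=whisker_low,
                whisker_high=whisker_high,
                outliers=outliers,
            )
        )
    return out


def boxplot_table(stats: list[BoxplotStats]) -> pd.DataFrame:
    """Boxplot statistics as a plot-ready DataFrame (one row per group)."""
    return pd.DataFrame(
        {
            "group": [s.group for s in stats],
            "n": [s.n for s in stats],
            "whisker_low": [s.whisker_low for s in stats],
            "q1": [s.q1 for s in stats],
            "median": [s.median for s in stats],
            "q3": [s.q3 for s in stats],
            "whisker_high": [s.whisker_high for s in stats],
            "outliers": [";".join(f"{v:.6g}" for v in s.outliers) for s in stats],
        }
    )
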