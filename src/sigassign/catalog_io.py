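"""Mutational channel schemas, COSMIC-style matrix I/O and SBS-96 classification.

Catalogs and signature sets are exchanged as tab-separated tables in the
COSMIC layout: a ``MutationType`` column holding channel labels followed by
one column per sample (integer counts) or per signature (probabilities).
Single base substitutions are classified into the 96-channel schema
(substitution type x flanking bases, pyrimidine-strand normalized); the
doublet (DBS-78), indel (ID-83) and copy-number (CN-48) schemas are supported
through pre-built matrices whose channel labels are taken from the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "SBS96_LABELS",
    "ChannelSchema",
    "MutationalCatalog",
    "SignatureSet",
    "MutationRecord",
    "ActivityMatrix",
    "sbs96_schema",
    "custom_schema",
    "classify_sbs96",
    "read_catalog",
    "write_catalog",
    "read_signatures",
    "write_signatures",
    "read_mutations",
    "build_catalog_from_mutations",
    "read_activities",
    "write_activities",
]

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical SBS-96 channel labels: substitution class major-sorted
#: (C>A, C>G, C>T, T>A, T>C, T>G), then 5' and 3' flanks in A, C, G, T order.
SBS96_LABELS = tuple(
    f"{p5}[{sub}]{p3}" for sub in _SUBSTITUTIONS for p5 in _BASES for p3 in _BASES
)

_SBS96_INDEX = {label: i for i, label in enumerate(SBS96_LABELS)}

# Channel counts of the fixed non-SBS schemas; label text is free-form and
# comes from the file header rows.
_SCHEMA_SIZES = {"SBS96": 96, "DBS78": 78, "ID83": 83, "CN48": 48}


@dataclass
class ChannelSchema:
    """An ordered mutational channel classification.

    Parameters
    ----------
    name:
        One of ``SBS96``, ``DBS78``, ``ID83``, ``CN48`` or ``CUSTOM``.
    channels:
        Ordered, unique channel labels. For ``SBS96`` these must be the
        canonical 96 labels in canonical order.
    """

    name: str
    channels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        if self.name == "SBS96":
            if self.channels != SBS96_LABELS:
                raise SchemaError("SBS96 schema requires the canonical 96 labels in canonical order")
        elif self.name in _SCHEMA_SIZES:
            if len(self.channels) != _SCHEMA_SIZES[self.name]:
                raise SchemaError(
                    f"{self.name} schema requires {_SCHEMA_SIZES[self.name]} channels, "
                    f"got {len(self.channels)}"
                )
        elif self.name != "CUSTOM":
            raise SchemaError(f"unknown schema name {self.name!r}")
        self._index = {label: i for i, label in enumerate(self.channels)}

    @property
    def size(self) -> int:
        return len(self.channels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise SchemaError(f"label {label!r} is not a channel of schema {self.name}") from None


def sbs96_schema() -> ChannelSchema:
    """The canonical 96-channel single-base-substitution schema."""
    return ChannelSchema("SBS96", SBS96_LABELS)


def custom_schema(channels, name: str = "CUSTOM") -> ChannelSchema:
    """A schema with caller-supplied channel labels (free-form order)."""
    return ChannelSchema(name, tuple(channels))


def _infer_schema(labels: tuple[str, ...]) -> ChannelSchema:
    if len(labels) == 96 and set(labels) == set(SBS96_LABELS):
        return sbs96_schema()
    for name, size in _SCHEMA_SIZES.items():
        if name != "SBS96" and len(labels) == size:
            return ChannelSchema(name, labels)
    return ChannelSchema("CUSTOM", labels)


def classify_sbs96(context: str, ref: str, alt: str) -> int:
    """Classify a single base substitution into its SBS-96 channel index.

    ``context`` is the reference-strand trinucleotide centered on the mutated
    base. Substitutions at purine reference bases are reverse-complemented so
    every channel is reported on the pyrimidine strand.

    Returns the index into :data:`SBS96_LABELS`.
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise ValidationError(f"trinucleotide context must have length 3, got {context!r}")
    if any(b not in _COMPLEMENT for b in context + ref + alt):
        raise ValidationError(f"non-ACGT base in ({context!r}, {ref!r}, {alt!r})")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValidationError(f"invalid substitution {ref!r}>{alt!r}")
    if context[1] != ref:
        raise ValidationError(f"context center {context[1]!r} does not match ref {ref!r}")
    if ref in "AG":  # purine reference: report on the pyrimidine strand
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return _SBS96_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


@dataclass
class MutationalCatalog:
    """Channel-count matrix (channels x samples) under a fixed schema."""

    schema: ChannelSchema
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (self.schema.size, len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{self.schema.size} channels x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(counts)):
            raise ValidationError("catalog counts must be finite")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValidationError("catalog counts must be nonnegative integers")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def burdens(self) -> np.ndarray:
        """Total mutation count of each sample (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class SignatureSet:
    """Column-stochastic signature profiles (channels x signatures).

    Columns whose sum deviates from 1 by at most 1e-3 (COSMIC files carry
    rounded probabilities) are renormalized exactly on construction; a larger
    deviation or any negative entry is a validation error.
    """

    schema: ChannelSchema
    signature_ids: list[str]
    profiles: np.ndarray

    #: Maximum tolerated deviation of a column sum from 1 before erroring.
    COLUMN_SUM_TOLERANCE = 1e-3

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=np.float64)
        if profiles.ndim != 2 or profiles.shape != (self.schema.size, len(self.signature_ids)):
            raise ValidationError(
                f"profiles shape {profiles.shape} does not match "
                f"{self.schema.size} channels x {len(self.signature_ids)} signatures"
            )
        if len(set(self.signature_ids)) != len(self.signature_ids):
            raise ValidationError("duplicate signature ids")
        if not np.all(np.isfinite(profiles)):
            raise ValidationError("signature profiles must be finite")
        if np.any(profiles < 0):
            raise ValidationError("signature profiles must be nonnegative")
        sums = profiles.sum(axis=0)
        bad = np.abs(sums - 1.0) > self.COLUMN_SUM_TOLERANCE
        if np.any(bad):
            which = [self.signature_ids[i] for i in np.flatnonzero(bad)]
            raise ValidationError(
                f"signature column sums deviate from 1 by more than "
                f"{self.COLUMN_SUM_TOLERANCE}: {which}"
            )
        self.profiles = profiles / sums

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)


@dataclass
class MutationRecord:
    """One somatic mutation from a mutation-list input (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str | None = None
    channel_index: int | None = None

    def __post_init__(self) -> None:
        self.pos = int(self.pos)
        if self.context is not None:
            self.context = self.context.upper()
            if len(self.context) != 3:
                raise ValidationError(
                    f"context for {self.sample_id} {self.chrom}:{self.pos} must be a "
                    f"trinucleotide, got {self.context!r}"
                )


@dataclass
class ActivityMatrix:
    """Integer signature activities (signatures x samples)."""

    signature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != (len(self.signature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"activity shape {values.shape} does not match "
                f"{len(self.signature_ids)} signatures x {len(self.sample_ids)} samples"
            )
        if np.any(values < 0) or np.any(values != np.round(values)):
            raise ValidationError("activities must be nonnegative integers")
        self.values = values.astype(np.int64)


# ---------------------------------------------------------------------------
# table reading helpers


def _read_matrix_table(path) -> tuple[tuple[str, ...], list[str], np.ndarray]:
    """Read a COSMIC-layout TSV; returns (row labels, column ids, values)."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").rstrip("\r")
    columns = header.split("\t")
    if len(columns) < 2:
        raise ValidationError(f"{path}: expected a label column plus at least one data column")
    ids = columns[1:]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate column ids in header")
    frame = pd.read_csv(path, sep="\t", header=None, names=columns, skiprows=1, dtype={columns[0]: str})
    labels = tuple(frame[columns[0]].astype(str))
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate channel labels")
    values = frame[ids].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric entries in data columns")
    return labels, ids, values.astype(np.float64)


def _resolve_schema(labels: tuple[str, ...], schema) -> ChannelSchema:
    if schema == "auto" or schema is None:
        resolved = _infer_schema(labels)
    else:
        resolved = schema
    if set(labels) != set(resolved.channels):
        missing = sorted(set(resolved.channels) - set(labels))[:5]
        extra = sorted(set(labels) - set(resolved.channels))[:5]
        raise SchemaError(
            f"channel labels do not match schema {resolved.name} "
            f"(missing e.g. {missing}, unexpected e.g. {extra})"
        )
    return resolved


def read_catalog(path, schema="auto") -> MutationalCatalog:
    """Read a mutational catalog; rows are reordered to canonical schema order."""
    labels, sample_ids, values = _read_matrix_table(path)
    resolved = _resolve_schema(labels, schema)
    order = [labels.index(label) for label in resolved.channels]
    counts = values[order, :]
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValidationError(f"{path}: catalog counts must be nonnegative integers")
    return MutationalCatalog(resolved, list(sample_ids), counts)


def write_catalog(catalog: MutationalCatalog, path) -> None:
    frame = pd.DataFrame(catalog.counts, columns=catalog.sample_ids)
    frame.insert(0, "MutationType", list(catalog.schema.channels))
    frame.to_csv(path, sep="\t", index=False)


def read_signatures(path, schema="auto") -> SignatureSet:
    """Read a signature matrix; columns are renormalized to sum exactly to 1."""
    labels, signature_ids, values = _read_matrix_table(path)
    resolved = _resolve_schema(labels, schema)
    order = [labels.index(label) for label in resolved.channels]
    return SignatureSet(resolved, list(signature_ids), values[order, :])


def write_signatures(signatures: SignatureSet, path) -> None:
    frame = pd.DataFrame(signatures.profiles, columns=signatures.signature_ids)
    frame.insert(0, "MutationType", list(signatures.schema.channels))
    frame.to_csv(path, sep="\t", index=False, float_format="%.18g")


_MUTATION_COLUMNS = ("sample", "chrom", "pos", "ref", "alt", "context")


def read_mutations(path) -> list[MutationRecord]:
    """Read a mutation list (TSV with header sample/chrom/pos/ref/alt/context)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in frame.columns}
    missing = [c for c in _MUTATION_COLUMNS if c not in lower]
    if missing:
        raise ValidationError(f"{path}: mutation list is missing columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        ref = str(getattr(row, lower["ref"]))
        alt = str(getattr(row, lower["alt"]))
        if len(ref) != 1 or len(alt) != 1 or "," in alt:
            raise ValidationError(
                f"{path}: only biallelic single-base substitutions are supported, "
                f"got {ref!r}>{alt!r}"
            )
        records.append(
            MutationRecord(
                sample_id=str(getattr(row, lower["sample"])),
                chrom=str(getattr(row, lower["chrom"])),
                pos=int(getattr(row, lower["pos"])),
                ref=ref,
                alt=alt,
                context=str(getattr(row, lower["context"])),
            )
        )
    return records


def build_catalog_from_mutations(
    records: list[MutationRecord], schema: ChannelSchema | None = None
) -> tuple[MutationalCatalog, list[MutationRecord]]:
    """Classify SBS records and aggregate them into a per-sample catalog.

    Records are annotated in place with their ``channel_index``. Samples
    appear in the catalog in order of first appearance in ``records``.
    """
    if schema is None:
        schema = sbs96_schema()
    if schema.name != "SBS96":
        raise ValidationError("mutation-list classification is only available for SBS96")
    sample_ids: list[str] = []
    sample_pos: dict[str, int] = {}
    for record in records:
        if record.context is None:
            raise ValidationError(
                f"mutation {record.sample_id} {record.chrom}:{record.pos} "
                f"{record.ref}>{record.alt} has no trinucleotide context"
            )
        record.channel_index = classify_sbs96(record.context, record.ref, record.alt)
        if record.sample_id not in sample_pos:
            sample_pos[record.sample_id] = len(sample_ids)
            sample_ids.append(record.sample_id)
    counts = np.zeros((schema.size, len(sample_ids)), dtype=np.int64)
    for record in records:
        counts[record.channel_index, sample_pos[record.sample_id]] += 1
    return MutationalCatalog(schema, sample_ids, counts), records


def write_activities(activities: ActivityMatrix, path) -> None:
    """Write an activity table: samples as rows, signatures as columns."""
    frame = pd.DataFrame(
        activities.values.T, index=activities.sample_ids, columns=activities.signature_ids
    )
    frame.index.name = "Samples"
    frame.to_csv(path, sep="\t")


def read_activities(path) -> ActivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy().T
    return ActivityMatrix(list(frame.columns), [str(s) for s in frame.index], values)
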