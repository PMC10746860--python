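"""Probabilistic attribution of individual somatic mutations to signatures.

Given a sample's fitted activities ``a`` and the signature profiles ``S``,
the probability that a mutation observed in channel ``k`` was generated by
signature ``i`` is the activity-weighted share of that channel:

    P(i | k) = S[k, i] * a[i] / sum_j S[k, j] * a[j]

Channels where every active signature carries zero mass have an undefined
posterior; such rows are emitted as zeros and flagged rather than NaN.
Probabilities are computed from the integer (rounded) activities so they are
consistent with the published activity tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog_io import ChannelSchema, MutationRecord, SignatureSet
from .exceptions import ValidationError

__all__ = [
    "ProbabilityTable",
    "MutationAttribution",
    "channel_probabilities",
    "attribute_mutations",
    "write_mutation_probabilities",
]

logger = logging.getLogger(__name__)


@dataclass
class ProbabilityTable:
    """Per-channel posterior signature probabilities for one sample."""

    sample_id: str
    schema: ChannelSchema
    signature_ids: list[str]
    probs: np.ndarray  # channels x signatures
    undefined: np.ndarray  # boolean mask of channels with zero fitted mass


@dataclass
class MutationAttribution:
    """A mutation record joined with its channel's probability row."""

    record: MutationRecord
    channel_label: str
    probabilities: np.ndarray
    undefined: bool


def channel_probabilities(
    signatures: SignatureSet, activities, sample_id: str = ""
) -> ProbabilityTable:
    """Posterior signature probabilities for every channel of one sample."""
    a = np.asarray(activities, dtype=np.float64)
    if a.shape != (signatures.n_signatures,):
        raise ValidationError(
            f"activity vector length {a.shape} does not match "
            f"{signatures.n_signatures} signatures"
        )
    if np.any(a < 0):
        raise ValidationError("activities must be nonnegative")
    weighted = signatures.profiles * a  # channels x signatures
    denom = weighted.sum(axis=1)
    undefined = denom <= 0.0
    probs = np.zeros_like(weighted)
    defined = ~undefined
    probs[defined] = weighted[defined] / denom[defined, None]
    return ProbabilityTable(sample_id, signatures.schema, list(signatures.signature_ids), probs, undefined)


def attribute_mutations(
    records: list[MutationRecord], table: ProbabilityTable
) -> list[MutationAttribution]:
    """Join classified mutation records with their channel probability rows."""
    out = []
    for record in records:
        if record.channel_index is None:
            raise ValidationError(
                f"mutation {record.sample_id} {record.chrom}:{record.pos} is not classified"
            )
        if not 0 <= record.channel_index < table.schema.size:
            raise ValidationError(f"channel index {record.channel_index} out of range")
        k = record.channel_index
        if table.undefined[k]:
            logger.warning(
                "mutation %s %s:%d falls in channel %s with no fitted signature mass",
                record.sample_id, record.chrom, record.pos, table.schema.channels[k],
            )
        out.append(
            MutationAttribution(
                record=record,
                channel_label=table.schema.channels[k],
                probabilities=table.probs[k].copy(),
                undefined=bool(table.undefined[k]),
            )
        )
    return out


def write_mutation_probabilities(
    attributions: list[MutationAttribution], signature_ids: list[str], path
) -> None:
    """Write one row per mutation with 6-decimal signature probabilities."""
    rows = []
    for att in attributions:
        row = {
            "Sample": att.record.sample_id,
            "Chrom": att.record.chrom,
            "Pos": att.record.pos,
            "Ref": att.record.ref,
            "Alt": att.record.alt,
            "MutationType": att.channel_label,
        }
        row.update(
            {sig: f"{p:.6f}" for sig, p in zip(signature_ids, att.probabilities)}
        )
        rows.append(row)
    columns = ["Sample", "Chrom", "Pos", "Ref", "Alt", "MutationType", *signature_ids]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
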