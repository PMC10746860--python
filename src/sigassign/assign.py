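"""Forward-stagewise assignment of known signatures to individual samples.

Starting from the full reference set, each sample's signature set is pruned
and re-grown around nonnegative least squares refits: a signature is removed
while the cheapest single removal raises the relative reconstruction error
by at most ``removal_tolerance`` (default 0.01), and a signature is added
back while the best single addition lowers it by at least ``addition_gain``
(default 0.05). The two passes alternate until the selected set is stable.
Final real-valued activities are rescaled to the sample's mutation burden
and rounded to integers with a largest-remainder scheme, so activities sum
exactly to the number of observed mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .catalog_io import ActivityMatrix, MutationalCatalog, SignatureSet
from .exceptions import ValidationError
from .nnls import calc_nnls, relative_error, solve_nnls

__all__ = [
    "AssignmentOptions",
    "AuditEvent",
    "SampleAssignment",
    "ActivityMatrix",
    "remove_signatures",
    "add_signatures",
    "round_activities",
    "assign_sample",
    "assign_samples",
    "assign_catalog",
]

logger = logging.getLogger(__name__)


@dataclass
class AssignmentOptions:
    """Tuning knobs of the stagewise selection loop.

    removal_tolerance:
        Maximum increase in relative error accepted when dropping one
        signature (absolute difference of relative errors).
    addition_gain:
        Minimum decrease in relative error required to add one signature.
    max_outer_iterations:
        Hard cap on remove/add alternations; the loop converges in a few
        iterations in practice, the cap only guards against cycling.
    rescale_to_burden:
        Rescale real-valued activities so the integer activities sum exactly
        to the sample's mutation burden before largest-remainder rounding.
    """

    removal_tolerance: float = 0.01
    addition_gain: float = 0.05
    max_outer_iterations: int = 100
    rescale_to_burden: bool = True

    def __post_init__(self) -> None:
        if self.removal_tolerance < 0:
            raise ValidationError("removal_tolerance must be >= 0")
        if self.addition_gain <= 0:
            raise ValidationError("addition_gain must be > 0")
        if self.max_outer_iterations < 1:
            raise ValidationError("max_outer_iterations must be >= 1")


@dataclass
class AuditEvent:
    """One considered stagewise step (the best candidate of one round)."""

    step: str  # "remove" or "add"
    signature: str
    eps_before: float
    eps_candidate: float
    accepted: bool


@dataclass
class SampleAssignment:
    sample_id: str
    selected_signature_ids: tuple[str, ...]
    activities: np.ndarray  # integer, over ALL reference signatures
    final_relative_error: float
    iterations_used: int
    audit: list[AuditEvent] = field(default_factory=list)


def _refit(v: np.ndarray, S_all: np.ndarray, sel: list[int]) -> tuple[float, np.ndarray]:
    M = S_all[:, sel]
    a = solve_nnls(M, v)
    return relative_error(v, M, a), a


def _remove_pass(v, S_all, ids, sel, eps_min, a_cur, tol, audit):
    """Drop signatures one at a time while the cheapest removal costs <= tol.

    A column with zero fitted activity can be dropped without refitting: the
    restricted solution is unchanged, so its removal error equals the current
    error exactly. When such columns exist the lowest-index one is removed;
    otherwise every single-column removal is refit and the arg-min taken
    (ties broken by lowest column index).
    """
    while len(sel) > 1:
        zero = np.flatnonzero(a_cur <= 0.0)
        if zero.size:
            j = int(zero[0])
            eps_cand, a_cand = eps_min, np.delete(a_cur, j)
        else:
            eps_cand, j, a_cand = np.inf, -1, None
            for cand in range(len(sel)):
                eps_c, a_c = _refit(v, S_all, sel[:cand] + sel[cand + 1 :])
                if eps_c < eps_cand:
                    eps_cand, j, a_cand = eps_c, cand, a_c
        accepted = eps_cand - eps_min <= tol
        audit.append(AuditEvent("remove", ids[sel[j]], eps_min, eps_cand, accepted))
        if not accepted:
            break
        del sel[j]
        a_cur, eps_min = a_cand, eps_cand
    return eps_min, sel, a_cur


def _add_pass(v, S_all, ids, sel, eps_min, a_cur, gain, audit):
    """Add signatures one at a time while the best addition gains >= gain."""
    n = S_all.shape[1]
    while True:
        selected = set(sel)
        candidates = [p for p in range(n) if p not in selected]
        if not candidates:
            return eps_min, sel, a_cur
        eps_cand, best, a_cand = np.inf, -1, None
        for p in candidates:
            eps_c, a_c = _refit(v, S_all, sel + [p])
            if eps_c < eps_cand:
                eps_cand, best, a_cand = eps_c, p, a_c
        accepted = eps_min - eps_cand >= gain
        audit.append(AuditEvent("add", ids[best], eps_min, eps_cand, accepted))
        if not accepted:
            return eps_min, sel, a_cur
        sel = sel + [best]
        a_cur, eps_min = a_cand, eps_cand


def remove_signatures(v, S, eps_min, tol=0.01, audit=None):
    """Stagewise removal on a raw design matrix; returns ``(eps, S', kept)``.

    ``kept`` lists the surviving column indices of the input ``S``; pass an
    ``audit`` list to capture the per-round :class:`AuditEvent` trail.
    """
    v = np.asarray(v, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    ids = [str(j) for j in range(S.shape[1])]
    sel = list(range(S.shape[1]))
    _, a_cur = _refit(v, S, sel)
    eps, sel, _ = _remove_pass(v, S, ids, sel, eps_min, a_cur, tol,
                               audit if audit is not None else [])
    return eps, S[:, sel], sel


def add_signatures(v, S_all, selected, eps_min, gain=0.05, audit=None):
    """Stagewise addition from ``S_all``; returns ``(eps, S', selected')``.

    ``selected`` holds the column indices of ``S_all`` currently in the model
    (in selection order); added signatures are appended. Pass an ``audit``
    list to capture the per-round :class:`AuditEvent` trail.
    """
    v = np.asarray(v, dtype=np.float64)
    S_all = np.asarray(S_all, dtype=np.float64)
    ids = [str(j) for j in range(S_all.shape[1])]
    sel = list(selected)
    _, a_cur = _refit(v, S_all, sel)
    eps, sel, _ = _add_pass(v, S_all, ids, sel, eps_min, a_cur, gain,
                            audit if audit is not None else [])
    return eps, S_all[:, sel], sel


def round_activities(a_real, total: int, rescale: bool = True) -> np.ndarray:
    """Convert real activities to integers.

    With ``rescale`` the vector is scaled to sum to ``total`` and rounded by
    largest remainder (ties to the lowest index), so the integers sum to
    ``total`` exactly; otherwise each entry is rounded half-up independently.
    """
    a = np.asarray(a_real, dtype=np.float64)
    if np.any(a < 0):
        raise ValidationError("activities must be nonnegative")
    if not rescale:
        return np.floor(a + 0.5).astype(np.int64)
    s = a.sum()
    if total == 0 or s <= 0.0:
        return np.zeros(a.shape, dtype=np.int64)
    # normalize before scaling: a/s <= 1 elementwise, so no overflow even
    # for subnormal sums
    scaled = (a / s) * float(total)
    floors = np.floor(scaled)
    remainder = int(round(total - floors.sum()))
    if remainder > 0:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:remainder]] += 1
    return floors.astype(np.int64)


def assign_sample(
    v, signatures: SignatureSet, options: AssignmentOptions | None = None, sample_id: str = ""
) -> SampleAssignment:
    """Assign signature activities to one sample's channel-count vector."""
    opts = options or AssignmentOptions()
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (signatures.schema.size,):
        raise ValidationError(
            f"sample vector length {v.shape} does not match schema size {signatures.schema.size}"
        )
    if np.any(v < 0) or np.any(v != np.round(v)):
        raise ValidationError("sample counts must be nonnegative integers")
    n = signatures.n_signatures
    ids = signatures.signature_ids
    burden = int(v.sum())
    if burden == 0:
        return SampleAssignment(sample_id, (), np.zeros(n, dtype=np.int64), 0.0, 0, [])

    S_all = signatures.profiles
    audit: list[AuditEvent] = []
    sel = list(range(n))
    eps_min, a_cur = _refit(v, S_all, sel)
    iterations = 0
    for iterations in range(1, opts.max_outer_iterations + 1):
        before = set(sel)
        eps_min, sel, a_cur = _remove_pass(
            v, S_all, ids, sel, eps_min, a_cur, opts.removal_tolerance, audit
        )
        eps_min, sel, a_cur = _add_pass(
            v, S_all, ids, sel, eps_min, a_cur, opts.addition_gain, audit
        )
        if set(sel) == before:
            break
    else:
        logger.warning(
            "sample %s: stagewise loop hit the iteration cap (%d)",
            sample_id, opts.max_outer_iterations,
        )

    eps_final, a_real = calc_nnls(v, S_all[:, sel])
    integer = round_activities(a_real, burden, rescale=opts.rescale_to_burden)
    activities = np.zeros(n, dtype=np.int64)
    activities[sel] = integer
    selected_ids = tuple(ids[j] for j in sorted(sel))
    return SampleAssignment(sample_id, selected_ids, activities, eps_final, iterations, audit)


def assign_samples(
    catalog: MutationalCatalog, signatures: SignatureSet, options: AssignmentOptions | None = None
) -> list[SampleAssignment]:
    """Run :func:`assign_sample` independently on every catalog column."""
    if catalog.schema.channels != signatures.schema.channels:
        raise ValidationError(
            f"catalog schema {catalog.schema.name} does not match "
            f"signature schema {signatures.schema.name}"
        )
    return [
        assign_sample(catalog.counts[:, s], signatures, options, sample_id=sample)
        for s, sample in enumerate(catalog.sample_ids)
    ]


def assign_catalog(
    catalog: MutationalCatalog, signatures: SignatureSet, options: AssignmentOptions | None = None
) -> ActivityMatrix:
    """Per-sample stagewise assignment of a whole catalog."""
    results = assign_samples(catalog, signatures, options)
    values = (
        np.stack([r.activities for r in results], axis=1)
        if results
        else np.zeros((signatures.n_signatures, 0), dtype=np.int64)
    )
    return ActivityMatrix(list(signatures.signature_ids), list(catalog.sample_ids), values)
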