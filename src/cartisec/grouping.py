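"""Response-group classification and summary statistics.

Proteins significant against control are sorted into three release
profiles: Group I (decreased release under cytokines and/or
injury+cytokines), Group II (increased release under cytokines alone)
and Group III (increased release under injury+cytokines, with or
without an increase under cytokines alone). A presence rule guards
against imputation bias: a protein must be observed in at least three
timepoints for one treatment condition across all animals.
Dexamethasone effects are called per contrast (D|N, CD|C, ICD|IC) and a
protein whose three calls agree carries a consistent-Dex label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .data_model import (
    DEX_CONSISTENCY_CONTRASTS,
    RosterEntry,
    ValidationError,
)
from .diffstats import DifferentialRecord

logger = logging.getLogger(__name__)

GROUPS = ("I", "II", "III")


@dataclass
class GroupAssignment:
    """Response class and Dex-effect calls for one protein."""

    protein_id: str
    group: str  # "I" | "II" | "III" | "none"
    passed_presence: bool
    dex_calls: dict[str, str] = field(default_factory=dict)
    dex_consistent: str = "no_change"
    conflicting: bool = False


@dataclass
class GroupSummary:
    """Counts and percentages over the grouped proteins."""

    n_I: int
    n_II: int
    n_III: int
    n_total: int
    pct_increased: float
    pct_decreased: float
    n_dex_decreased: int
    n_dex_increased: int
    pct_dex_decreased: float
    pct_dex_increased: float
    pct_III_dex_reduced: float


def passes_presence(mask: pd.DataFrame, protein: str) -> bool:
    """True iff some treatment has >= 3 observed timepoints in every animal.

    ``mask`` is the pre-imputation presence mask (protein x
    (animal, treatment) counts of non-missing days).
    """
    if protein not in mask.index:
        raise ValidationError(f"protein {protein!r} absent from presence mask")
    counts = mask.loc[protein].unstack("animal")  # treatment x animal
    return bool((counts >= 3).all(axis=1).any())


def _sig_dir(record: DifferentialRecord, alpha: float, use_adjusted: bool):
    p = record.p_adj if use_adjusted else record.p
    return p <= alpha, record.direction


def classify_protein(
    c_record: DifferentialRecord,
    ic_record: DifferentialRecord,
    passed_presence: bool,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> str:
    """Assign the Group I/II/III label from the C|N and IC|N contrasts.

    Group III takes precedence over Group II when both contrasts are
    significantly up ("C alone" defines Group II). A protein significant
    in opposite directions across the two contrasts is labeled "none"
    and logged as conflicting.
    """
    if not passed_presence:
        return "none"
    sig_c, dir_c = _sig_dir(c_record, alpha, use_adjusted)
    sig_ic, dir_ic = _sig_dir(ic_record, alpha, use_adjusted)
    up_c, up_ic = sig_c and dir_c == "up", sig_ic and dir_ic == "up"
    down_c, down_ic = sig_c and dir_c == "down", sig_ic and dir_ic == "down"
    if (up_c and down_ic) or (down_c and up_ic):
        logger.warning(
            "protein %s significant in opposite directions for C|N and IC|N; "
            "left ungrouped",
            c_record.protein_id,
        )
        return "none"
    if up_ic:
        return "III"
    if up_c and not sig_ic:
        return "II"
    if down_c or down_ic:
        return "I"
    return "none"


def classify_dex_effect(
    records: dict[str, DifferentialRecord],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[dict[str, str], str]:
    """Per-contrast Dex calls and the consistency verdict.

    ``records`` maps contrast labels to differential records and must
    contain the three consistency contrasts D|N, CD|C, ICD|IC (an ID|I
    record, if supplied, is called and reported but excluded from the
    consistency verdict). A call is increase/decrease when significant
    with that sign, else no_change; the verdict is the common call when
    all three agree (all-no_change included), else "inconsistent".
    """
    missing = [c for c in DEX_CONSISTENCY_CONTRASTS if c not in records]
    if missing:
        raise ValidationError(f"missing Dex contrast(s) {missing}")
    calls: dict[str, str] = {}
    for label, record in records.items():
        sig, direction = _sig_dir(record, alpha, use_adjusted)
        calls[label] = (
            ("increase" if direction == "up" else "decrease") if sig else "no_change"
        )
    core = {calls[c] for c in DEX_CONSISTENCY_CONTRASTS}
    consistent = core.pop() if len(core) == 1 else "inconsistent"
    return calls, consistent


def classify_all(
    records: list[DifferentialRecord],
    mask: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> list[GroupAssignment]:
    """Full classification over the proteins of a contrast result set."""
    by_protein: dict[str, dict[str, DifferentialRecord]] = {}
    for r in records:
        by_protein.setdefault(r.protein_id, {})[r.contrast] = r
    assignments = []
    for protein, recs in by_protein.items():
        for needed in ("C|N", "IC|N"):
            if needed not in recs:
                raise ValidationError(
                    f"protein {protein} lacks contrast {needed}"
                )
        presence = passes_presence(mask, protein)
        group = classify_protein(
            recs["C|N"], recs["IC|N"], presence, alpha, use_adjusted
        )
        dex_records = {
            label: recs[label]
            for label in (*DEX_CONSISTENCY_CONTRASTS, "ID|I")
            if label in recs
        }
        if all(c in dex_records for c in DEX_CONSISTENCY_CONTRASTS):
            dex_calls, dex_consistent = classify_dex_effect(
                dex_records, alpha, use_adjusted
            )
        else:
            dex_calls, dex_consistent = {}, "no_change"
        assignments.append(
            GroupAssignment(
                protein_id=protein,
                group=group,
                passed_presence=presence,
                dex_calls=dex_calls,
                dex_consistent=dex_consistent,
                conflicting=group == "none"
                and presence
                and _is_conflicting(recs, alpha, use_adjusted),
            )
        )
    return assignments


def _is_conflicting(recs, alpha, use_adjusted) -> bool:
    sig_c, dir_c = _sig_dir(recs["C|N"], alpha, use_adjusted)
    sig_ic, dir_ic = _sig_dir(recs["IC|N"], alpha, use_adjusted)
    return sig_c and sig_ic and dir_c != dir_ic


def _pct(numerator: int, denominator: int) -> float:
    """Percentage, reported to the nearest integer (one decimal below 10%)."""
    value = 100.0 * numerator / denominator
    return round(value, 1) if value < 10 else float(round(value))


def summarize(assignments: list[GroupAssignment]) -> GroupSummary:
    """Headline counts and percentages over the grouped proteins.

    A protein counts as Dex-decreased (-increased) if at least one of
    its Dex contrasts was called in that direction.
    """
    grouped = [a for a in assignments if a.group in GROUPS]
    if not grouped:
        raise ValidationError("no grouped proteins to summarize")
    n = {g: sum(1 for a in grouped if a.group == g) for g in GROUPS}
    total = len(grouped)
    dex_dec = [a for a in grouped if "decrease" in a.dex_calls.values()]
    dex_inc = [a for a in grouped if "increase" in a.dex_calls.values()]
    n_iii = n["III"]
    n_iii_reduced = sum(1 for a in dex_dec if a.group == "III")
    return GroupSummary(
        n_I=n["I"],
        n_II=n["II"],
        n_III=n["III"],
        n_total=total,
        pct_increased=_pct(n["II"] + n["III"], total),
        pct_decreased=_pct(n["I"], total),
        n_dex_decreased=len(dex_dec),
        n_dex_increased=len(dex_inc),
        pct_dex_decreased=_pct(len(dex_dec), total),
        pct_dex_increased=_pct(len(dex_inc), total),
        pct_III_dex_reduced=_pct(n_iii_reduced, n_iii) if n_iii else 0.0,
    )


def roster_to_assignments(roster: list[RosterEntry]) -> list[GroupAssignment]:
    """View the published roster as group assignments for `summarize`.

    The per-protein Dex direction from the printed typography key stands
    in for the per-contrast calls; dex-only entries (no group) pass
    through with group "none".
    """
    out = []
    for entry in roster:
        out.append(
            GroupAssignment(
                protein_id=entry.gene_symbol,
                group=entry.group or "none",
                passed_presence=True,
                dex_calls={"table": entry.dex_direction},
                dex_consistent=entry.dex_consistent or "no_change",
            )
        )
    return out


def assignments_to_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {
            "protein": a.protein_id,
            "group": a.group,
            "passed_presence": a.passed_presence,
            "dex_consistent": a.dex_consistent,
            "conflicting": a.conflicting,
        }
        for label, call in a.dex_calls.items():
            row[f"dex[{label}]"] = call
        rows.append(row)
    return pd.DataFrame(rows)
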