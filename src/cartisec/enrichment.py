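"""Bootstrap test of subcellular-localization over-representation.

For a response group of proteins and a background set (typically all
differentially released proteins), the observed proportion of the
group annotated to a category (intracellular or extracellular) is
compared with the distribution of that proportion over resamples of
the same size drawn from the background with replacement. The p-value
uses the add-one estimator, so it can never be exactly zero; its
resolution at the default 10,000 repeats is 1/10,001.

Proteins annotated "both" count toward both categories; "unknown"
counts toward neither and is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ValidationError

_CATEGORIES = ("intracellular", "extracellular")


@dataclass
class EnrichmentResult:
    group_label: str
    category: str
    n_group: int
    observed_prop: float
    background_prop: float
    unknown_prop: float
    n_boot: int
    p_upper: float
    p_lower: float
    p_boot: float
    tail: str
    seed: int | None


def _membership(annotation: pd.DataFrame, proteins: list[str], category: str):
    loc = annotation.set_index("protein")["localization"]
    missing = [p for p in proteins if p not in loc.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} protein(s) lack annotation, e.g. {missing[:3]}"
        )
    values = loc.loc[proteins]
    member = (values == category) | (values == "both")
    return member.to_numpy(dtype=bool), (values == "unknown").to_numpy(dtype=bool)


def bootstrap_proportion_test(
    group: list[str] | set[str],
    background: list[str] | set[str],
    annotation: pd.DataFrame,
    category: str,
    n_boot: int = 10_000,
    seed: int | None = None,
    group_label: str = "",
) -> EnrichmentResult:
    """One-sided bootstrap p-value for a category proportion.

    The tail is chosen by the direction of departure of the observed
    proportion from the background proportion; both tail p-values are
    reported. Deterministic for a fixed seed.
    """
    if category not in _CATEGORIES:
        raise ValidationError(f"category must be one of {_CATEGORIES}")
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    group = sorted(set(map(str, group)))
    background = sorted(set(map(str, background)))
    if not group:
        raise ValidationError("empty protein group")
    extra = set(group) - set(background)
    if extra:
        raise ValidationError(
            f"group is not a subset of the background ({sorted(extra)[:3]}...)"
        )
    g_member, _ = _membership(annotation, group, category)
    b_member, b_unknown = _membership(annotation, background, category)
    observed = float(g_member.mean())
    bg_prop = float(b_member.mean())

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(background), size=(n_boot, len(group)))
    props = b_member[draws].mean(axis=1)
    p_upper = float((1 + np.sum(props >= observed)) / (n_boot + 1))
    p_lower = float((1 + np.sum(props <= observed)) / (n_boot + 1))
    tail = "upper" if observed >= bg_prop else "lower"
    return EnrichmentResult(
        group_label=group_label,
        category=category,
        n_group=len(group),
        observed_prop=observed,
        background_prop=bg_prop,
        unknown_prop=float(b_unknown.mean()),
        n_boot=n_boot,
        p_upper=p_upper,
        p_lower=p_lower,
        p_boot=p_upper if tail == "upper" else p_lower,
        tail=tail,
        seed=seed,
    )
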