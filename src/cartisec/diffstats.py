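"""Within-animal contrasts with empirical-Bayes moderated t-statistics.

The design pairs treatments within each animal, so a contrast reduces
to a one-sample test on the three within-animal log2 fold changes of
summed abundance. With only two residual degrees of freedom per
protein, per-protein variances are noisy; they are shrunk toward a
prior variance s0^2 with prior degrees of freedom d0, both estimated
across proteins by fitting a scaled F distribution to the observed
sample variances via the method of moments on log s^2 (digamma /
trigamma moment matching, Newton inversion of the trigamma equation).
The moderated statistic

    t = mean / sqrt(s_tilde^2 / n),
    s_tilde^2 = (d0 * s0^2 + d_g * s^2) / (d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom
(standard normal in the complete-shrinkage limit d0 = infinity).
Benjamini-Hochberg step-up adjustment is applied within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

from .data_model import ContrastSpec, Treatment, ValidationError

#: Variance floor applied on the log scale during hyperparameter
#: fitting; avoids -inf moments when imputation makes all three
#: within-animal ratios identical.
VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class EBHyperparams:
    """Shrinkage prior of the moderated-t model.

    ``d0`` may be ``inf`` (complete shrinkage: the observed spread of
    log variances is no larger than expected from sampling alone).
    """

    d0: float
    s0_sq: float
    n_proteins_used: int

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValidationError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be > 0")


@dataclass
class DifferentialRecord:
    """Per-protein result of one pairwise contrast."""

    protein_id: str
    contrast: str
    fc_by_animal: tuple[float, ...]
    mean_log2fc: float
    s_sq: float
    t_mod: float
    df_total: float
    p: float
    p_adj: float
    direction: str


@dataclass
class PCAResult:
    """Scores, loadings and percent variance of a centered, scaled PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained: np.ndarray


def per_animal_log2fc(summed: pd.DataFrame, contrast: ContrastSpec) -> pd.DataFrame:
    """Within-animal log2 fold changes of summed abundance.

    ``summed`` is the protein x (animal, treatment) log2 summed matrix;
    the result is protein x animal with fc = test - reference.
    """
    animals = summed.columns.get_level_values("animal").unique()
    for t in (contrast.test, contrast.reference):
        if t.value not in summed.columns.get_level_values("treatment"):
            raise ValidationError(f"summed matrix lacks treatment {t.value}")
    test = summed.loc[:, [(a, contrast.test.value) for a in animals]]
    ref = summed.loc[:, [(a, contrast.reference.value) for a in animals]]
    if test.isna().any().any() or ref.isna().any().any():
        raise ValidationError("summed matrix has missing cells for this contrast")
    fc = test.to_numpy() - ref.to_numpy()
    return pd.DataFrame(fc, index=summed.index, columns=list(animals))


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_eb_hyperparams(
    s_sq: np.ndarray | list[float], d_g: float = 2.0
) -> EBHyperparams:
    """Fit the scaled-F variance prior (d0, s0^2) across proteins.

    Matches the mean and spread of log s^2 against the moments implied
    by s^2 ~ s0^2 * F(d_g, d0): with e = log s^2 - digamma(d_g/2) +
    log(d_g/2), E[e] = log s0^2 + digamma(d0/2) - log(d0/2) and
    Var[e] = trigamma(d_g/2) + trigamma(d0/2). The excess of the
    empirical spread over the sampling term trigamma(d_g/2) identifies
    d0; no excess means complete shrinkage (d0 = inf) with s0^2 the
    geometric-mean-based estimate exp(mean(e)).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    if len(s_sq) < 2:
        raise ValidationError("need at least two finite variances")
    if np.all(s_sq <= 0):
        raise ValidationError("all variances are zero")
    s_sq = np.maximum(s_sq, VAR_FLOOR)
    n = len(s_sq)
    z = np.log(s_sq)
    e = z - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(polygamma(1, d_g / 2.0))
    if excess <= 0:
        return EBHyperparams(d0=np.inf, s0_sq=float(np.exp(e_mean)), n_proteins_used=n)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBHyperparams(d0=d0, s0_sq=s0_sq, n_proteins_used=n)


def moderated_t_test(
    fc_by_animal: np.ndarray | list[float],
    s_sq: float,
    hyper: EBHyperparams,
) -> tuple[float, float, float]:
    """Moderated one-sample t on the within-animal fold changes.

    Returns (t_mod, df_total, two-sided p). ``d0 = 0`` reduces to the
    ordinary one-sample t; ``d0 = inf`` is complete shrinkage with a
    normal reference distribution.
    """
    fc = np.asarray(fc_by_animal, dtype=float)
    n = len(fc)
    d_g = n - 1
    mean = float(np.mean(fc))
    if np.isinf(hyper.d0):
        s_post = hyper.s0_sq
        df_total = np.inf
    else:
        s_post = (hyper.d0 * hyper.s0_sq + d_g * s_sq) / (hyper.d0 + d_g)
        df_total = hyper.d0 + d_g
    if s_post <= 0:
        raise ValidationError("posterior variance is not positive")
    t_mod = mean / np.sqrt(s_post / n)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(abs(t_mod), df_total)
    return float(t_mod), float(df_total), float(min(p, 1.0))


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def run_contrasts(
    summed: pd.DataFrame,
    contrasts: list[ContrastSpec] | tuple[ContrastSpec, ...],
) -> list[DifferentialRecord]:
    """Moderated within-animal tests for a set of pairwise contrasts.

    One shrinkage-prior fit per contrast over all proteins, then
    per-protein moderated tests and BH adjustment within the contrast.
    """
    records: list[DifferentialRecord] = []
    for contrast in contrasts:
        fc = per_animal_log2fc(summed, contrast)
        values = fc.to_numpy()
        means = values.mean(axis=1)
        s_sq = values.var(axis=1, ddof=1)
        hyper = fit_eb_hyperparams(s_sq, d_g=values.shape[1] - 1)
        stats_rows = [
            moderated_t_test(values[i], s_sq[i], hyper)
            for i in range(len(fc))
        ]
        p = np.array([row[2] for row in stats_rows])
        p_adj = bh_adjust(p)
        for i, protein in enumerate(fc.index):
            t_mod, df_total, p_i = stats_rows[i]
            records.append(
                DifferentialRecord(
                    protein_id=str(protein),
                    contrast=contrast.label,
                    fc_by_animal=tuple(float(v) for v in values[i]),
                    mean_log2fc=float(means[i]),
                    s_sq=float(s_sq[i]),
                    t_mod=t_mod,
                    df_total=df_total,
                    p=p_i,
                    p_adj=float(p_adj[i]),
                    direction="up" if means[i] >= 0 else "down",
                )
            )
    return records


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Flatten differential records into a writable table."""
    rows = []
    for r in records:
        row = {
            "protein": r.protein_id,
            "contrast": r.contrast,
        }
        for k, v in enumerate(r.fc_by_animal, start=1):
            row[f"fc_a{k}"] = v
        row.update(
            mean_log2fc=r.mean_log2fc,
            s_sq=r.s_sq,
            t_mod=r.t_mod,
            df=r.df_total,
            p=r.p,
            p_adj=r.p_adj,
            direction=r.direction,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pca(samples_by_variable: pd.DataFrame) -> PCAResult:
    """Centered, unit-scaled PCA via singular value decomposition.

    Rows are observations (samples), columns are variables (proteins).
    Variables are standardized (SD denominator n - 1, matching the
    usual center/scale convention) before decomposition; at most
    min(n_samples - 1, n_variables) components are returned and their
    percent variances sum to 100.
    """
    X = samples_by_variable.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA requires at least two samples")
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        offenders = list(samples_by_variable.columns[zero][:5])
        raise ValidationError(f"zero-variance variable(s): {offenders}")
    Z = (X - X.mean(axis=0)) / sd
    k = min(n - 1, p)
    u, s, vt = linalg.svd(Z, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    scores = u * s
    eig = s**2
    var_explained = 100.0 * eig / eig.sum()
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=samples_by_variable.index, columns=comp),
        loadings=pd.DataFrame(
            vt.T, index=samples_by_variable.columns, columns=comp
        ),
        var_explained=var_explained,
    )


def heatmap_order(
    summed_z: pd.DataFrame, method: str = "ward"
) -> tuple[list[str], np.ndarray]:
    """Hierarchical (Euclidean) protein ordering for heatmap display.

    Returns the dendrogram leaf order over proteins (rows of
    ``summed_z``) and the linkage matrix, so callers can cut the tree.
    Ward linkage on Euclidean distances is used by default.
    """
    if summed_z.isna().any().any():
        raise ValidationError("heatmap ordering requires a complete matrix")
    if len(summed_z) < 2:
        return list(summed_z.index), np.empty((0, 4))
    Z = hierarchy.linkage(summed_z.to_numpy(), method=method, metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    return [str(summed_z.index[i]) for i in leaves], Z
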