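"""Two-group differential expression with empirical-Bayes variance moderation.

The workflow mirrors the standard moderated-t analysis of log2 expression
matrices: per-gene group means and pooled variances, shrinkage of the
variances toward a common prior estimated by the method of moments on the
log variances (digamma/trigamma matching), moderated t statistics with
augmented degrees of freedom, Benjamini-Hochberg FDR adjustment, and
threshold-based gene selection. Fold-change helpers convert between the
log2 and natural scales, including the comparative-Ct (2^-ddCt) quantity
used for qRT-PCR validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "GeneSet",
    "fit_group_means",
    "moderate_variances",
    "adjust_bh",
    "select_de",
    "log2fc_to_absfc",
    "top_table",
    "ddct_fold_change",
    "trigamma_inverse",
]

#: Column order of a written DE table.
DE_COLUMNS = ["gene", "mean_a", "mean_b", "log2fc", "abs_fc",
              "s2", "df", "t", "p", "q"]


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique upper-cased gene symbols.

    Order is preserved (e.g. ranking by fold change) but membership is
    set-like; ``provenance`` records how the set was built (contrast,
    thresholds) so screens can check it.
    """

    name: str
    members: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        seen, ordered = set(), []
        for m in self.members:
            u = str(m).upper()
            if u not in seen:
                seen.add(u)
                ordered.append(u)
        object.__setattr__(self, "members", tuple(ordered))

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.members)


def _group_masks(samples: Sequence[str], groups: Sequence[str],
                 contrast: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    if len(groups) != len(samples):
        raise ValueError(
            f"got {len(groups)} group labels for {len(samples)} samples")
    g = np.asarray(groups, dtype=object)
    a, b = contrast
    mask_a, mask_b = g == a, g == b
    for label, mask in ((a, mask_a), (b, mask_b)):
        if mask.sum() < 2:
            raise ValueError(
                f"contrast group {label!r} has {int(mask.sum())} samples; need >=2")
    return mask_a, mask_b


def fit_group_means(matrix: pd.DataFrame, groups: Sequence[str],
                    contrast: tuple[str, str]) -> pd.DataFrame:
    """Per-gene two-group contrast statistics before moderation.

    Parameters
    ----------
    matrix
        log2 expression, genes in rows, samples in columns.
    groups
        One label per sample (column order).
    contrast
        ``(group_a, group_b)``; the log2 fold change is
        ``mean(group_a) - mean(group_b)``.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b, log2fc,
    s2 (pooled within-group variance), df (nA + nB - 2); sample sizes are
    stored in ``attrs``.
    """
    mask_a, mask_b = _group_masks(matrix.columns, groups, contrast)
    xa = matrix.loc[:, mask_a].to_numpy(dtype=float)
    xb = matrix.loc[:, mask_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ssa = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    out = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "log2fc": mean_a - mean_b,
         "s2": s2, "df": float(df)},
        index=matrix.index.copy(),
    )
    out.index.name = "gene"
    out.attrs.update({"n_a": na, "n_b": nb, "contrast": tuple(contrast)})
    return out


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the monotone decreasing, convex shape of the trigamma function;
    the standard iteration on 1/trigamma converges quickly from the
    large-y approximation trigamma(y) ~ 1/y.
    """
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def _estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior to the
    sample variances via their logs: returns (d0, s0_squared); d0 may be inf
    when the variances are no more dispersed than chi-square sampling alone
    explains."""
    pos = s2[s2 > 0]
    if pos.size < 10:
        raise ValueError("need >=10 genes with positive variance to estimate the prior")
    z = np.log(pos)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) * (pos.size - 1) / pos.size - \
        float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_2 = math.exp(e_mean)
    return d0, s0_2


def moderate_variances(table: pd.DataFrame, d0: float | None = None,
                       s0_2: float | None = None) -> pd.DataFrame:
    """Add moderated t statistics and two-sided p-values to a contrast table.

    The per-gene variance is shrunk toward a common prior variance
    ``s0_2`` with prior degrees of freedom ``d0``::

        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        t = log2fc / sqrt(s2_post * (1/nA + 1/nB))

    with p-values from a t distribution on ``df + d0`` degrees of freedom.
    ``d0 = 0`` reduces to the ordinary two-sample t; ``d0 = inf`` uses the
    common variance for every gene. When not given, (d0, s0_2) are estimated
    by moment matching on log variances; if estimation fails the ordinary t
    (d0 = 0) is used with a warning.
    """
    out = table.copy()
    s2 = out["s2"].to_numpy(dtype=float)
    df = float(out["df"].iloc[0])
    na, nb = table.attrs["n_a"], table.attrs["n_b"]

    if np.all(s2 == 0):
        raise ValueError(
            "all residual variances are zero; add noise or pass d0/s0_2 explicitly")

    if d0 is None or (d0 > 0 and s0_2 is None):
        try:
            est = _estimate_prior(s2, df)
        except ValueError as exc:
            warnings.warn(
                f"variance-prior estimation failed ({exc}); "
                "falling back to the ordinary t (d0=0)", RuntimeWarning)
            est = (0.0, float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0)
        if d0 is None:
            d0 = est[0]
        if s0_2 is None:
            s0_2 = est[1]
    if s0_2 is None:
        s0_2 = 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = out["log2fc"].to_numpy() / se
    t = np.where(np.isfinite(t), t, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    out["abs_fc"] = 2.0 ** np.abs(out["log2fc"])
    out["q"] = adjust_bh(p)
    out.attrs.update(table.attrs)
    out.attrs.update({"d0": d0, "s0_2": s0_2})
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, returned in the
    input order. Stable under ties and invariant to permutations of the
    input.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_de(table: pd.DataFrame, lfc_cut: float, q_cut: float,
              direction: str = "up", name: str | None = None) -> GeneSet:
    """Select differentially expressed genes by fold-change and FDR cuts.

    ``direction='up'`` keeps log2fc >= lfc_cut, ``'down'`` keeps
    log2fc <= -lfc_cut, ``'both'`` keeps |log2fc| >= lfc_cut; all require
    q <= q_cut. Members are ordered by descending |log2fc|.
    """
    if lfc_cut < 0:
        raise ValueError("lfc_cut must be nonnegative")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if "q" not in table.columns:
        raise ValueError("table must be moderated and BH-adjusted first")
    lfc = table["log2fc"]
    if direction == "up":
        mask = lfc >= lfc_cut
    elif direction == "down":
        mask = lfc <= -lfc_cut
    else:
        mask = lfc.abs() >= lfc_cut
    mask &= table["q"] <= q_cut
    sel = table.loc[mask].sort_values("log2fc", key=np.abs, ascending=False)
    contrast = table.attrs.get("contrast")
    if name is None:
        name = f"{contrast[0]}_vs_{contrast[1]}_{direction}" if contrast \
            else f"de_{direction}"
    return GeneSet(name=name, members=tuple(sel.index.astype(str)),
                   provenance={"lfc_cut": lfc_cut, "q_cut": q_cut,
                               "direction": direction, "contrast": contrast})


def log2fc_to_absfc(lfc: float, signed: bool = False):
    """Convert a log2 fold change to the natural ('absolute') fold change.

    ``signed=False`` returns ``2**lfc``. ``signed=True`` returns
    ``(2**|lfc|, direction)`` with direction +1/-1 (0 maps to +1), matching
    the convention of quoting down-regulation as an absolute fold change
    with a direction flag.
    """
    if not math.isfinite(lfc):
        raise ValueError("log2 fold change must be finite")
    if not signed:
        return 2.0 ** lfc
    return 2.0 ** abs(lfc), (1 if lfc >= 0 else -1)


def top_table(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top ``n`` genes by descending log2 fold change.

    Ties are broken by ascending q (when present), then by gene id.
    ``n`` larger than the table returns everything.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    work = table.copy()
    work["_gene"] = work.index.astype(str)
    by = ["log2fc"] + (["q"] if "q" in work.columns else []) + ["_gene"]
    asc = [False] + ([True] if "q" in work.columns else []) + [True]
    work = work.sort_values(by, ascending=asc, kind="stable")
    return work.drop(columns="_gene").head(n)


def ddct_fold_change(ct: Mapping[str, Mapping[str, float]]) -> float:
    """Comparative-Ct fold change, 2^-ddCt.

    ``ct`` maps the conditions ``"sample"`` and ``"calibrator"`` to their
    ``"target"`` and ``"housekeeping"`` Ct values. Per condition
    dCt = Ct_target - Ct_housekeeping; ddCt = dCt_sample - dCt_calibrator;
    the fold change relative to the calibrator is 2^-ddCt.
    """
    dct = {}
    for cond in ("sample", "calibrator"):
        if cond not in ct:
            raise ValueError(f"missing condition {cond!r} in Ct table")
        row = ct[cond]
        for role in ("target", "housekeeping"):
            if role not in row or row[role] is None:
                raise ValueError(f"missing {role} Ct for condition {cond!r}")
            if not row[role] > 0:
                raise ValueError(f"Ct values must be positive ({cond}/{role})")
        dct[cond] = float(row["target"]) - float(row["housekeeping"])
    ddct = dct["sample"] - dct["calibrator"]
    return 2.0 ** (-ddct)
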