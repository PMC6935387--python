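"""Group statistics: event-vs-control comparisons, qualitative summary
tables, threshold fractions, and discriminative k-mer enrichment.

Two-group feature comparisons use Welch's unpaired two-sided t test with a
Kolmogorov-Smirnov normality flag attached per group (informational; the
test runs regardless).  P-values are adjusted across a table by Bonferroni
or Benjamini-Hochberg, and verdicts (higher / lower / no significant
difference) are driven by the adjusted values.

Motif enrichment is a discriminative k-mer presence/absence test with a
label-permutation null: for every k-mer common enough in the foreground,
the statistic is the difference in the per-sequence presence fraction
between foreground and background.  This replaces EM-style motif discovery
with an exactly testable statistic over the same question — are specific
short sequences over-represented in mis-spliced items relative to their
matched controls?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

VERDICT_HIGHER = "higher"
VERDICT_LOWER = "lower"
VERDICT_NONE = "no_significant_difference"


@dataclass
class ComparisonResult:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    verdict: str | None = None
    ks_normal_a: bool | None = None
    ks_normal_b: bool | None = None


def _ks_normal(values: np.ndarray) -> bool:
    """KS test against a fitted normal; True when normality is not rejected
    at 0.05.  Degenerate (zero-variance) samples count as non-normal."""
    sd = values.std(ddof=1)
    if sd == 0:
        return False
    z = (values - values.mean()) / sd
    return stats.kstest(z, "norm").pvalue >= 0.05


def compare_groups(
    values_a, values_b, feature: str = "", group_a: str = "a", group_b: str = "b"
) -> ComparisonResult:
    """Welch's unpaired two-sided t test of group A vs group B."""
    a = np.asarray([v for v in values_a if v is not None], dtype=float)
    b = np.asarray([v for v in values_b if v is not None], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need at least 2 values per group (got {len(a)}, {len(b)})"
        )
    if np.array_equal(a, b):
        stat, p = 0.0, 1.0  # identical samples; Welch denominator may be 0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        statistic=stat,
        p_value=p,
        ks_normal_a=_ks_normal(a),
        ks_normal_b=_ks_normal(b),
    )


def adjust_pvalues(
    results: list[ComparisonResult], method: str = "bh", alpha: float = 0.05
) -> list[ComparisonResult]:
    """Set ``p_adjusted`` (Bonferroni or Benjamini-Hochberg) and recompute
    verdicts against ``alpha``.  Results are modified in place and returned."""
    if not results:
        raise ValueError("no results to adjust")
    raw = [r.p_value for r in results]
    if method == "bonferroni":
        adj = np.minimum(1.0, np.asarray(raw) * len(raw))
    elif method == "bh":
        adj = multipletests(raw, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    for r, p_adj in zip(results, adj):
        r.p_adjusted = float(p_adj)
        if p_adj >= alpha:
            r.verdict = VERDICT_NONE
        else:
            r.verdict = VERDICT_HIGHER if r.mean_a > r.mean_b else VERDICT_LOWER
    return results


def fraction_below(values, threshold: float) -> float:
    """Fraction of values strictly below the threshold."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("empty value list")
    return sum(1 for v in vals if v < threshold) / len(vals)


def summarize_feature_table(
    grouped_values: dict[str, dict[str, list]],
    event_groups: list[str],
    internal_group: str,
    external_group: str,
    method: str = "bh",
    alpha: float = 0.05,
) -> tuple[list[dict], list[ComparisonResult]]:
    """Qualitative summary of every feature x event-group cell.

    ``grouped_values[feature][group]`` holds the raw per-item values.  For
    each feature and event group, the group is compared against the internal
    and external controls separately; p-values are adjusted across the whole
    table; and a verdict phrase is composed from which controls differ and
    in which direction (e.g. "lower than internal and external controls").
    Cells with fewer than two usable values on either side are marked
    ``not_computed``.
    """
    comparisons: list[ComparisonResult] = []
    cells: list[dict] = []
    pending: list[tuple[dict, dict[str, ComparisonResult]]] = []
    for feature, by_group in grouped_values.items():
        for g in event_groups:
            cell = {"feature": feature, "group": g}
            per_control: dict[str, ComparisonResult] = {}
            for label, ctrl in (("internal", internal_group), ("external", external_group)):
                vals_g = [v for v in by_group.get(g, []) if v is not None]
                vals_c = [v for v in by_group.get(ctrl, []) if v is not None]
                if len(vals_g) < 2 or len(vals_c) < 2:
                    continue
                res = compare_groups(vals_g, vals_c, feature=feature,
                                     group_a=g, group_b=ctrl)
                per_control[label] = res
                comparisons.append(res)
            pending.append((cell, per_control))
    if comparisons:
        adjust_pvalues(comparisons, method=method, alpha=alpha)
    for cell, per_control in pending:
        if not per_control:
            cell["verdict"] = "not_computed"
        else:
            cell["verdict"] = _verdict_phrase(per_control)
        for label, res in per_control.items():
            cell[f"p_{label}"] = res.p_value
            cell[f"p_adj_{label}"] = res.p_adjusted
        cells.append(cell)
    return cells, comparisons


def _verdict_phrase(per_control: dict[str, ComparisonResult]) -> str:
    sig = {
        lab: res.verdict
        for lab, res in per_control.items()
        if res.verdict != VERDICT_NONE
    }
    if not sig:
        return "no significant difference"
    parts = []
    for direction in (VERDICT_LOWER, VERDICT_HIGHER):
        labs = sorted(lab for lab, v in sig.items() if v == direction)
        if labs:
            parts.append(f"{direction} than {' and '.join(labs)} controls")
    return "; ".join(parts)


def stop_codon_fraction(consequences: list[str]) -> float:
    """Fraction of retained introns classified as carrying an in-frame stop."""
    if not consequences:
        raise ValueError("no consequence calls")
    return sum(1 for c in consequences if c == "in_frame_stop") / len(consequences)


@dataclass
class MotifHit:
    kmer: str
    fg_freq: float
    bg_freq: float
    enrichment: float
    p_perm: float
    p_adjusted: float


_CODE_MAP = np.full(256, -1, dtype=np.int64)
for _b, _i in zip("ACGT", range(4)):
    _CODE_MAP[ord(_b)] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Unique integer codes (base-4) of all k-mers in a sequence; windows
    containing non-ACGT symbols are skipped."""
    v = _CODE_MAP[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(v) < k:
        return np.empty(0, dtype=np.int64)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(v, k)
    ok = (win >= 0).all(axis=1)
    pw = 4 ** np.arange(k - 1, -1, -1)
    return np.unique((win[ok] * pw).sum(axis=1))


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_enrichment(
    fg: list[str],
    bg: list[str],
    k_min: int = 5,
    k_max: int = 8,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    min_fg_frac: float = 0.2,
    alpha: float = 0.05,
) -> list[MotifHit]:
    """Discriminative k-mer enrichment with a permutation null.

    For each k in [k_min, k_max], every k-mer present in at least
    ``min_fg_frac`` of foreground sequences is tested with the statistic
    fg presence fraction - bg presence fraction (presence/absence per
    sequence); the null permutes the fg/bg labels ``n_perm`` times;
    p-values are BH-adjusted across all tested k-mers.  Returns hits with
    adjusted p < alpha, sorted by enrichment (descending).
    """
    if not fg or not bg:
        raise ValueError("foreground and background must be nonempty")
    rng = rng or np.random.default_rng()

    all_seqs = list(fg) + list(bg)
    n_fg = len(fg)
    usable = [len(s) >= k_min for s in all_seqs]
    if not any(usable[:n_fg]) or not any(usable[n_fg:]):
        raise ValueError(f"all sequences shorter than k_min={k_min}")
    if not all(usable):
        log.warning("%d sequences shorter than k_min skipped", usable.count(False))

    # per-k presence columns, restricted to k-mers common in the foreground
    candidates: list[str] = []
    columns: list[np.ndarray] = []
    min_count = min_fg_frac * n_fg
    for k in range(k_min, k_max + 1):
        per_seq = [_kmer_codes(s, k) for s in all_seqs]
        counts: dict[int, int] = {}
        for codes in per_seq[:n_fg]:
            for c in codes.tolist():
                counts[c] = counts.get(c, 0) + 1
        cand = np.array(
            sorted(c for c, n in counts.items() if n >= min_count), dtype=np.int64
        )
        if cand.size == 0:
            continue
        pres = np.zeros((len(all_seqs), cand.size), dtype=np.float32)
        for i, codes in enumerate(per_seq):
            pres[i, np.searchsorted(cand, np.intersect1d(codes, cand))] = 1.0
        candidates.extend(_decode(int(c), k) for c in cand)
        columns.append(pres)
    if not candidates:
        return []
    mat = np.concatenate(columns, axis=1)
    labels_fg = np.zeros(len(all_seqs), dtype=np.float32)
    labels_fg[:n_fg] = 1.0
    n_bg = len(bg)
    observed = mat[:n_fg].mean(axis=0) - mat[n_fg:].mean(axis=0)

    # batched permutations: columns of L are permuted fg indicators
    perm_labels = np.empty((len(all_seqs), n_perm), dtype=np.float32)
    for p in range(n_perm):
        perm_labels[:, p] = rng.permutation(labels_fg)
    fg_means = mat.T @ perm_labels / n_fg  # (n_kmers, n_perm)
    totals = mat.sum(axis=0)[:, None]
    bg_means = (totals - fg_means * n_fg) / n_bg
    perm_stats = fg_means - bg_means
    exceed = (perm_stats >= observed[:, None]).sum(axis=1)
    p_perm = (1 + exceed) / (1 + n_perm)

    p_adj = multipletests(p_perm, method="fdr_bh")[1]
    fg_freq = mat[:n_fg].mean(axis=0)
    bg_freq = mat[n_fg:].mean(axis=0)
    hits = []
    for j, km in enumerate(candidates):
        if p_adj[j] < alpha:
            enr = fg_freq[j] / bg_freq[j] if bg_freq[j] > 0 else np.inf
            hits.append(
                MotifHit(
                    kmer=km,
                    fg_freq=float(fg_freq[j]),
                    bg_freq=float(bg_freq[j]),
                    enrichment=float(enr),
                    p_perm=float(p_perm[j]),
                    p_adjusted=float(p_adj[j]),
                )
            )
    hits.sort(key=lambda h: (-h.enrichment, h.kmer))
    return hits
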