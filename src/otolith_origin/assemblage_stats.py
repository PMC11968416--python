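"""Assemblage-level comparisons of natal-origin distributions.

Groups (species, families, reaches, years, consumed vs. independently
sampled prey) are compared on their refined origin-category counts with
r×c Fisher exact tests and a Bonferroni-adjusted alpha (nominal alpha
divided by the number of tests actually executed).

The exact test enumerates every contingency table with the observed
margins and sums the multivariate-hypergeometric probabilities of tables
no more probable than the observed one (with a 1+1e-7 relative guard
against floating-point ties). When the margin-constrained table count
exceeds ``enumeration_limit`` the p-value is estimated by Monte Carlo over
the fixed-margins null: column labels are randomly permuted against row
membership, which samples tables from exactly the conditional
(multivariate hypergeometric) distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ComparisonError

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (r, c), non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ComparisonError("counts must be a 2-D non-negative integer array")


@dataclass(frozen=True)
class TestResult:
    comparison_id: str
    p_value: float
    method: str  # "enumeration" | "monte_carlo" | "degenerate"
    n_tables_or_reps: int
    seed: int | None
    alpha_adjusted: float = float("nan")
    significant: bool = False
    table_shape: tuple[int, int] = (0, 0)
    n_total: int = 0
    skipped: bool = False
    reason: str = ""


def _log_factorials(n: int) -> np.ndarray:
    return gammaln(np.arange(n + 1) + 1.0)


def _log_table_prob(flat: np.ndarray, logfact: np.ndarray, const: float) -> float:
    """log P(T) under the fixed-margins multivariate hypergeometric."""
    return const - float(logfact[flat].sum())


class _EnumerationOverflow(Exception):
    pass


def _enumerate_tables(row_margins, col_margins, limit):
    """Yield flat table arrays with the given margins; abort past ``limit``."""
    r, c = len(row_margins), len(col_margins)
    table = np.zeros(r * c, dtype=np.int64)
    count = 0

    def rec(i: int, col_rem: np.ndarray):
        nonlocal count
        if i == r - 1:
            # last row forced by column margins
            table[i * c:(i + 1) * c] = col_rem
            count += 1
            if count > limit:
                raise _EnumerationOverflow
            yield table
            return
        ri = row_margins[i]
        # enumerate compositions of ri into c cells bounded by col_rem
        cells = np.zeros(c, dtype=np.int64)

        def fill(j: int, rem: int):
            if j == c - 1:
                if rem <= col_rem[j]:
                    cells[j] = rem
                    table[i * c:(i + 1) * c] = cells
                    yield from rec(i + 1, col_rem - cells)
                return
            tail_cap = int(col_rem[j + 1:].sum())
            lo = max(0, rem - tail_cap)
            hi = min(rem, int(col_rem[j]))
            for v in range(lo, hi + 1):
                cells[j] = v
                yield from fill(j + 1, rem - v)

        yield from fill(0, ri)

    yield from rec(0, np.asarray(col_margins, dtype=np.int64).copy())


def _prune(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    return t


def fisher_exact_rxc(
    table,
    enumeration_limit: int = 100_000,
    n_reps: int = 100_000,
    seed: int | None = None,
    method: str = "auto",
) -> TestResult:
    """Two-sided Fisher exact test for an r×c table of counts.

    ``method`` is ``"auto"`` (enumerate when the table count fits within
    ``enumeration_limit``, else Monte Carlo), ``"enumeration"`` or
    ``"monte_carlo"``. Monte Carlo requires a seed and reports
    ``(1 + #{P(T) <= P_obs}) / (n_reps + 1)``. Degenerate 1×c / r×1 tables
    return p = 1.
    """
    t = _prune(np.asarray(table, dtype=np.int64))
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult("", 1.0, "degenerate", 0, seed,
                          table_shape=tuple(np.asarray(table).shape),
                          n_total=int(np.asarray(table).sum()))
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    logfact = _log_factorials(n)
    const = float(logfact[rows].sum() + logfact[cols].sum() - logfact[n])
    flat_obs = t.ravel()
    logp_obs = _log_table_prob(flat_obs, logfact, const)
    cutoff = logp_obs + np.log1p(_REL_TOL)

    if method in ("auto", "enumeration"):
        try:
            total = 0.0
            count = 0
            limit = enumeration_limit if method == "auto" else np.inf
            for flat in _enumerate_tables(rows, cols, limit):
                lp = _log_table_prob(flat, logfact, const)
                count += 1
                if lp <= cutoff:
                    total += np.exp(lp)
            p = min(max(total, np.exp(logp_obs)), 1.0)
            return TestResult("", p, "enumeration", count, None,
                              table_shape=t.shape, n_total=n)
        except _EnumerationOverflow:
            if method == "enumeration":
                raise ComparisonError(
                    f"table count exceeds enumeration limit {enumeration_limit}"
                )
    if seed is None:
        raise ComparisonError("Monte Carlo p-value requires a seed")
    p = _monte_carlo_p(t, rows, cols, logfact, const, cutoff, n_reps, seed)
    return TestResult("", p, "monte_carlo", n_reps, seed,
                      table_shape=t.shape, n_total=n)


def _monte_carlo_p(
    t, rows, cols, logfact, const, cutoff, n_reps, seed, chunk: int = 20_000
) -> float:
    rng = np.random.default_rng(seed)
    r, c = t.shape
    n = int(t.sum())
    labels = np.repeat(np.arange(c), cols)
    row_of_pos = np.repeat(np.arange(r), rows)
    hits = 0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        # permute column labels within each replicate
        keys = rng.random((m, n))
        order = np.argsort(keys, axis=1)
        lab = labels[order]  # (m, n)
        code = row_of_pos[None, :] * c + lab
        counts = np.zeros((m, r * c), dtype=np.int64)
        rep_idx = np.repeat(np.arange(m), n)
        np.add.at(counts, (rep_idx, code.ravel()), 1)
        lp = const - logfact[counts].sum(axis=1)
        hits += int((lp <= cutoff).sum())
        done += m
    return (1 + hits) / (n_reps + 1)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Adjusted per-test alpha: alpha / n_tests."""
    if n_tests < 1:
        raise ComparisonError("n_tests must be >= 1")
    return alpha / n_tests


def build_contingency(
    assignments: pd.DataFrame,
    group_col: str,
    category_col: str = "refined",
    min_group_n: int = 5,
) -> ContingencyTable | None:
    """Cross-tabulate refined categories by group.

    Groups with fewer than ``min_group_n`` individuals are removed (the
    sample-size exclusion rule); empty category columns are pruned.
    Returns ``None`` when fewer than two groups survive.
    """
    df = assignments[[group_col, category_col]].dropna()
    sizes = df.groupby(group_col).size()
    keep = sizes[sizes >= min_group_n].index
    df = df[df[group_col].isin(keep)]
    if df[group_col].nunique() < 2:
        return None
    ct = pd.crosstab(df[group_col], df[category_col])
    ct = ct.loc[:, ct.sum(axis=0) > 0]
    return ContingencyTable(
        row_labels=tuple(str(i) for i in ct.index),
        col_labels=tuple(str(c) for c in ct.columns),
        counts=ct.to_numpy(dtype=np.int64),
    )


def harmonize_external_prey(
    external: pd.DataFrame,
    label_map: dict[str, str] | None = None,
    drop_out_of_limits: bool = True,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Align an external study's assignments with this study's labels.

    Applies ``label_map`` to the refined labels (identity for unmapped
    labels unless ``strict``) and removes records whose core chemistry was
    above/below the model limits. Returns the harmonised frame and removal
    counts.
    """
    from .classification import UNCLASSIFIABLE_ABOVE, UNCLASSIFIABLE_BELOW

    label_map = label_map or {}
    df = external.copy()
    if strict:
        unmapped = sorted(set(df["refined"]) - set(label_map))
        if unmapped:
            raise ComparisonError(f"unmapped external labels: {unmapped}")
    df["refined"] = df["refined"].map(lambda s: label_map.get(s, s))
    removed = 0
    if drop_out_of_limits and "coarse" in df.columns:
        mask = df["coarse"].isin([UNCLASSIFIABLE_ABOVE, UNCLASSIFIABLE_BELOW])
        removed = int(mask.sum())
        df = df[~mask]
    return df.reset_index(drop=True), {"removed_out_of_limits": removed}


def _classified(assignments: pd.DataFrame) -> pd.DataFrame:
    df = assignments
    df = df[~df["excluded_vaterite"].astype(bool)]
    if "error" in df.columns:
        df = df[(df["error"].isna()) | (df["error"] == "")]
    return df[df["coarse"] != ""]


def run_comparison_suite(
    assignments: pd.DataFrame,
    external: pd.DataFrame | None = None,
    external_taxon_map: dict[str, str] | None = None,
    alpha: float = 0.05,
    min_group_n: int = 5,
    enumeration_limit: int = 100_000,
    n_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise origin-distribution comparisons, Bonferroni-adjusted.

    Comparison families: predator species within each reach; each predator
    species across reaches; prey families within each reach; each prey
    family across reaches; collection years within each reach (consumed
    prey); consumed vs. external independently sampled prey per taxon
    pairing. Skipped comparisons (too few groups after the minimum-n rule)
    appear as skip records and do not count toward the Bonferroni divisor.
    """
    df = _classified(assignments)
    requests: list[tuple[str, pd.DataFrame, str]] = []
    seen: set[str] = set()

    def add(cid: str, sub: pd.DataFrame, group_col: str):
        if cid in seen:  # duplicate requests are deduplicated
            return
        seen.add(cid)
        requests.append((cid, sub, group_col))

    preds = df[df["role"] == "predator"]
    for pool in sorted(preds["pool"].dropna().unique()):
        sub = preds[preds["pool"] == pool]
        for a, b in itertools.combinations(sorted(sub["species"].unique()), 2):
            add(f"predators:{a}-vs-{b}:{pool}",
                sub[sub["species"].isin([a, b])], "species")
    for sp in sorted(preds["species"].dropna().unique()):
        sub = preds[preds["species"] == sp]
        for a, b in itertools.combinations(sorted(sub["pool"].unique()), 2):
            add(f"predator-reaches:{sp}:{a}-vs-{b}",
                sub[sub["pool"].isin([a, b])], "pool")

    prey = df[(df["role"] == "prey") & (df["source"] == "stomach")]
    for pool in sorted(prey["pool"].dropna().unique()):
        sub = prey[prey["pool"] == pool]
        for a, b in itertools.combinations(sorted(sub["family"].unique()), 2):
            add(f"prey-families:{a}-vs-{b}:{pool}",
                sub[sub["family"].isin([a, b])], "family")
    for fam in sorted(prey["family"].dropna().unique()):
        sub = prey[prey["family"] == fam]
        for a, b in itertools.combinations(sorted(sub["pool"].unique()), 2):
            add(f"prey-reaches:{fam}:{a}-vs-{b}",
                sub[sub["pool"].isin([a, b])], "pool")

    for pool in sorted(prey["pool"].dropna().unique()):
        sub = prey[prey["pool"] == pool]
        if sub["year"].nunique() >= 2:
            add(f"years:{pool}", sub, "year")

    if external is not None:
        ext, _ = harmonize_external_prey(external)
        taxon_map = external_taxon_map or {}
        for fam in sorted(prey["family"].dropna().unique()):
            ext_key = taxon_map.get(fam, fam)
            esub = ext[ext["family"] == ext_key]
            psub = prey[prey["family"] == fam]
            if esub.empty or psub.empty:
                continue
            merged = pd.concat(
                [psub.assign(study="consumed"), esub.assign(study="independent")],
                ignore_index=True,
            )
            add(f"consumed-vs-independent:{fam}", merged, "study")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(requests))]

    results: list[TestResult] = []
    for (cid, sub, group_col), cseed in zip(requests, child_seeds):
        ct = build_contingency(sub, group_col, min_group_n=min_group_n)
        if ct is None:
            results.append(TestResult(cid, float("nan"), "skipped", 0, None,
                                      skipped=True,
                                      reason="fewer than 2 groups of sufficient size"))
            continue
        res = fisher_exact_rxc(ct.counts, enumeration_limit, n_reps, cseed)
        results.append(TestResult(cid, res.p_value, res.method,
                                  res.n_tables_or_reps, res.seed,
                                  table_shape=res.table_shape, n_total=res.n_total))

    n_run = sum(1 for r in results if not r.skipped)
    alpha_adj = bonferroni(alpha, n_run) if n_run else float("nan")
    rows = []
    for r in results:
        rows.append(dict(
            comparison=r.comparison_id, p_value=r.p_value, method=r.method,
            n_tables_or_reps=r.n_tables_or_reps, seed=r.seed,
            alpha_adjusted=alpha_adj if not r.skipped else float("nan"),
            significant=(not r.skipped) and (r.p_value < alpha_adj),
            rows=r.table_shape[0], cols=r.table_shape[1], n=r.n_total,
            skipped=r.skipped, reason=r.reason,
        ))
    return pd.DataFrame(rows)
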