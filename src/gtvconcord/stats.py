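"""Cohort-level summaries, paired tests and report tables.

The reporting layout follows the clinical comparison of three contour
variants: per-group (Total/A/B/C) summaries of the 3D displacement vector,
volume, length, maximum transverse diameter, conformity index and degree of
inclusion, with Wilcoxon signed-rank tests for position/volume/CI/DI,
paired t tests for length and diameter, and Spearman correlation between
CI and the 3D vector.  Significance is read per comparison at P < 0.05; no
multiple-testing correction is applied by default (a Holm adjustment is
available but off, matching the per-comparison reading of the source
analyses).

Wilcoxon conventions (configurable): zero differences are dropped, ties are
mid-ranked, and the exact null distribution is used for n <= 25 pairs with
a continuity-corrected normal approximation above that — the common
SPSS-style behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PAIR_NAMES, VARIANT_NAMES

__all__ = [
    "SummaryStats",
    "TestResult",
    "summarize",
    "wilcoxon_paired",
    "paired_t",
    "spearman",
    "holm_adjust",
    "CohortResult",
    "build_tables",
    "build_tables_from_frame",
]

#: switch from exact to normal-approximation Wilcoxon above this many pairs
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class SummaryStats:
    """Median, quartiles (linear interpolation), mean and sample SD."""

    median: float
    iqr: tuple[float, float]
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome; ``degenerate`` flags undefined cases."""

    test_name: str
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False
    note: str = ""


def summarize(values) -> SummaryStats:
    """Descriptive summary of a sample (n >= 1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return SummaryStats(
        median=float(med), iqr=(float(q1), float(q3)),
        mean=float(x.mean()), sd=sd, n=int(x.size),
    )


def _degenerate(name: str, n: int, note: str) -> TestResult:
    return TestResult(
        test_name=name, statistic=float("nan"), p_value=float("nan"),
        n_pairs=n, degenerate=True, note=note,
    )


def wilcoxon_paired(
    a, b, zero_method: str = "wilcox", exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (``zero_method="wilcox"``), ties are
    mid-ranked.  With ``n <= exact_max_n`` usable pairs the exact null
    distribution is enumerated; otherwise a continuity-corrected normal
    approximation is used.  The reported statistic is the signed
    standardised Z of the positive-rank sum (tie-corrected variance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if zero_method == "wilcox":
        d_used = d[d != 0.0]
    else:
        d_used = d
    n = int(d_used.size)
    if n == 0:
        return _degenerate("wilcoxon", 0, "all paired differences are zero")
    if n < 2:
        return _degenerate("wilcoxon", n, "fewer than two nonzero differences")

    ranks = sps.rankdata(np.abs(d_used))
    w_plus = float(ranks[d_used > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)

    method = "exact" if n <= exact_max_n else "approx"
    try:
        res = sps.wilcoxon(
            d_used, zero_method="wilcox", correction=(method == "approx"),
            alternative="two-sided", method=method,
        )
        p = float(res.pvalue)
    except ValueError:
        res = sps.wilcoxon(
            d_used, zero_method="wilcox", correction=True,
            alternative="two-sided", method="approx",
        )
        p, method = float(res.pvalue), "approx"
    return TestResult(
        test_name="wilcoxon", statistic=float(z), p_value=p,
        n_pairs=n, note=method,
    )


def paired_t(a, b) -> TestResult:
    """Classical two-sided paired-sample t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return _degenerate("paired_t", int(a.size), "zero-variance differences")
    t, p = sps.ttest_rel(a, b)
    return TestResult(
        test_name="paired_t", statistic=float(t), p_value=float(p), n_pairs=int(a.size)
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranked ties, two-sided t-based P)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _degenerate("spearman", int(x.size), "constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        test_name="spearman", statistic=float(rho), p_value=float(p), n_pairs=int(x.size)
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_GROUP_ORDER = ("Total", "A", "B", "C")
_PAIR_KEYS = tuple(f"{a} and {b}" for a, b in PAIR_NAMES)
_DI_KEYS = tuple(
    f"{a} in {b}" for x, y in PAIR_NAMES for a, b in ((x, y), (y, x))
)


@dataclass
class CohortResult:
    """Per-group report tables plus every test outcome, JSON-serialisable."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    tests: dict[str, dict] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "tests.json", "w") as fh:
            json.dump(self.tests, fh, indent=2, sort_keys=True)

    def to_test_dict(self) -> dict:
        return self.tests


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.to_flat_dict() for r in records])


def _by_group(df: pd.DataFrame):
    yield "Total", df
    for g in ("A", "B", "C"):
        sub = df[df["group"] == g]
        if len(sub):
            yield g, sub
        else:
            warnings.warn(f"group {g} has no records; its table rows are omitted")


def _test_entry(res: TestResult) -> dict:
    return {
        "test": res.test_name, "statistic": None if np.isnan(res.statistic) else res.statistic,
        "p_value": None if np.isnan(res.p_value) else res.p_value,
        "n_pairs": res.n_pairs, "degenerate": res.degenerate, "note": res.note,
    }


def _safe(testfn, a, b) -> TestResult:
    try:
        return testfn(a, b)
    except ValueError as err:
        return _degenerate(testfn.__name__, len(a), str(err))


def build_tables(records, holm: bool = False) -> CohortResult:
    """Build the five report tables from per-patient metric records.

    ``records`` is a list of :class:`~gtvconcord.metrics.MetricRecord`.
    Tables (tidy long CSV layouts):

    * ``t2_vector_displacement`` — per group, mean ± SD of the 3D vector per
      contour pair, with pairwise Wilcoxon Z/P between the three vectors;
    * ``t3_volume`` — volume summaries (M, IQR, mean ± SD) per variant per
      group with pairwise Wilcoxon tests;
    * ``t4_length_diameter`` — length and maximum transverse diameter per
      variant per group with paired t tests;
    * ``t5_ci`` — CI summaries per pair with Wilcoxon comparisons and the
      Spearman correlation of CI against the 3D vector;
    * ``t6_di`` — all six ordered degree-of-inclusion summaries per group.
    """
    return build_tables_from_frame(_records_frame(records), holm=holm)


def build_tables_from_frame(df: pd.DataFrame, holm: bool = False) -> CohortResult:
    """As :func:`build_tables`, from an already-flattened metrics frame."""
    if df.empty:
        raise ValueError("no metric records supplied")
    result = CohortResult()
    result.group_sizes = {
        g: int(n) for g, n in (("Total", len(df)),
                               *df["group"].value_counts().items())
    }

    pair_combos = [
        (_PAIR_KEYS[0], _PAIR_KEYS[1]),
        (_PAIR_KEYS[0], _PAIR_KEYS[2]),
        (_PAIR_KEYS[1], _PAIR_KEYS[2]),
    ]
    variant_combos = [
        (VARIANT_NAMES[2], VARIANT_NAMES[1]),  # PET-reg vs PET-ref
        (VARIANT_NAMES[2], VARIANT_NAMES[0]),  # PET-reg vs 3D
        (VARIANT_NAMES[1], VARIANT_NAMES[0]),  # PET-ref vs 3D
    ]

    # T2 — 3D vector displacement -------------------------------------
    rows, tests = [], {}
    for g, sub in _by_group(df):
        for key in _PAIR_KEYS:
            s = summarize(sub[f"vector_v [{key}]"].dropna())
            rows.append({"group": g, "pair": key, "n": s.n,
                         "mean_mm": s.mean, "sd_mm": s.sd, "median_mm": s.median})
        for k1, k2 in pair_combos:
            res = _safe(wilcoxon_paired, sub[f"vector_v [{k1}]"].to_numpy(),
                        sub[f"vector_v [{k2}]"].to_numpy())
            tests[f"{g}: {k1} vs {k2}"] = _test_entry(res)
    result.tables["t2_vector_displacement"] = pd.DataFrame(rows)
    result.tests["t2_vector_wilcoxon"] = tests

    # T3 — volumes ------------------------------------------------------
    rows, tests = [], {}
    for g, sub in _by_group(df):
        for name in VARIANT_NAMES:
            s = summarize(sub[f"volume_cm3 [{name}]"].dropna())
            rows.append({"group": g, "structure": name, "n": s.n,
                         "median_cm3": s.median, "q1_cm3": s.iqr[0],
                         "q3_cm3": s.iqr[1], "mean_cm3": s.mean, "sd_cm3": s.sd})
        for v1, v2 in variant_combos:
            res = _safe(wilcoxon_paired, sub[f"volume_cm3 [{v1}]"].to_numpy(),
                        sub[f"volume_cm3 [{v2}]"].to_numpy())
            tests[f"{g}: {v1} vs {v2}"] = _test_entry(res)
    result.tables["t3_volume"] = pd.DataFrame(rows)
    result.tests["t3_volume_wilcoxon"] = tests

    # T4 — length and maximum transverse diameter ----------------------
    rows, tests = [], {}
    for g, sub in _by_group(df):
        for name in VARIANT_NAMES:
            sl = summarize(sub[f"length_cm [{name}]"].dropna())
            sd_ = summarize(sub[f"max_diameter_cm [{name}]"].dropna())
            rows.append({"group": g, "structure": name, "n": sl.n,
                         "length_mean_cm": sl.mean, "length_sd_cm": sl.sd,
                         "diameter_mean_cm": sd_.mean, "diameter_sd_cm": sd_.sd})
        for measure in ("length_cm", "max_diameter_cm"):
            for v1, v2 in variant_combos:
                res = _safe(paired_t, sub[f"{measure} [{v1}]"].to_numpy(),
                            sub[f"{measure} [{v2}]"].to_numpy())
                tests[f"{g}: {measure}: {v1} vs {v2}"] = _test_entry(res)
    result.tables["t4_length_diameter"] = pd.DataFrame(rows)
    result.tests["t4_paired_t"] = tests

    # T5 — conformity index --------------------------------------------
    rows, tests = [], {}
    for g, sub in _by_group(df):
        for key in _PAIR_KEYS:
            s = summarize(sub[f"ci [{key}]"].dropna())
            rows.append({"group": g, "pair": key, "n": s.n,
                         "median": s.median, "q1": s.iqr[0], "q3": s.iqr[1],
                         "mean": s.mean, "sd": s.sd})
        for k1, k2 in pair_combos:
            res = _safe(wilcoxon_paired, sub[f"ci [{k1}]"].to_numpy(),
                        sub[f"ci [{k2}]"].to_numpy())
            tests[f"{g}: {k1} vs {k2}"] = _test_entry(res)
    for key in _PAIR_KEYS:  # CI vs 3D vector, all patients
        try:
            res = spearman(df[f"ci [{key}]"].to_numpy(), df[f"vector_v [{key}]"].to_numpy())
        except ValueError as err:
            res = _degenerate("spearman", len(df), str(err))
        tests[f"spearman CI~V: {key}"] = _test_entry(res)
    result.tables["t5_ci"] = pd.DataFrame(rows)
    result.tests["t5_ci_tests"] = tests

    # T6 — degree of inclusion (six orderings) -------------------------
    rows, tests = [], {}
    for g, sub in _by_group(df):
        for key in _DI_KEYS:
            s = summarize(sub[f"di [{key}]"].dropna())
            rows.append({"group": g, "inclusion": key, "n": s.n,
                         "median": s.median, "q1": s.iqr[0], "q3": s.iqr[1],
                         "mean": s.mean, "sd": s.sd})
    # the headline DI comparison: PET-reg in 3D vs PET-ref in 3D (and reverse)
    for g, sub in _by_group(df):
        for ka, kb in (
            ("GTV_PET-reg in GTV_3D", "GTV_PET-ref in GTV_3D"),
            ("GTV_3D in GTV_PET-reg", "GTV_3D in GTV_PET-ref"),
            ("GTV_PET-reg in GTV_3D", "GTV_PET-reg in GTV_PET-ref"),
            ("GTV_PET-ref in GTV_PET-reg", "GTV_3D in GTV_PET-reg"),
        ):
            res = _safe(wilcoxon_paired, sub[f"di [{ka}]"].to_numpy(),
                        sub[f"di [{kb}]"].to_numpy())
            tests[f"{g}: {ka} vs {kb}"] = _test_entry(res)
    result.tables["t6_di"] = pd.DataFrame(rows)
    result.tests["t6_di_wilcoxon"] = tests

    if holm:
        for block in result.tests.values():
            keys = [k for k, v in block.items() if v["p_value"] is not None]
            if keys:
                adj = holm_adjust([block[k]["p_value"] for k in keys])
                for k, padj in zip(keys, adj):
                    block[k]["p_holm"] = float(padj)
    return result
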