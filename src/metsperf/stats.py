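"""Study statistics: log-transformed t-tests on rCBV, group comparisons,
size-rCBV correlation, and longitudinal paired tests.

rCBV values are natural-log transformed before every t-test (their
distribution is right-skewed and approximately lognormal); means ± s.e.
are still reported on the original scale.  Tumor sizes are tested on the
raw scale.  Tests are two-sided and no multiple-testing correction is
applied, matching the source analysis; lesions are pooled across animals,
ignoring within-animal correlation - a limitation that is flagged rather
than "fixed" in the rendered report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One test: group summaries on the original scale, t and p."""

    test: str
    groups: Tuple[str, ...]
    n: Tuple[int, ...]
    means: Tuple[float, ...]           # arithmetic means, original scale
    sems: Tuple[float, ...]
    medians: Tuple[float, ...]
    ranges: Tuple[Tuple[float, float], ...]
    t: float
    p: float
    transform: str = "log"
    n_excluded: int = 0

    def summary(self) -> str:
        parts = [
            f"{g}: n={n}, mean={m:.3f}±{s:.3f} (s.e.), median={md:.2f}, "
            f"range {lo:.2f}-{hi:.2f}"
            for g, n, m, s, md, (lo, hi)
            in zip(self.groups, self.n, self.means, self.sems,
                   self.medians, self.ranges)
        ]
        return f"{self.test}: " + "; ".join(parts) + \
            f"; t={self.t:.3f}, p={self.p:.4g} ({self.transform} scale)"


def _describe(x: np.ndarray):
    return (len(x), float(np.mean(x)),
            float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan"),
            float(np.median(x)), (float(np.min(x)), float(np.max(x))))


def _safe_rel_ttest(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def paired_test_rcbv(tumor: Sequence[float], normal: Sequence[float],
                     labels: Tuple[str, str] = ("tumor", "contralateral_normal")
                     ) -> StatResult:
    """Paired t-test of tumor vs contralateral rCBV on the natural-log scale.

    Rows with a non-positive value on either side are excluded (the log is
    undefined there) and counted in ``n_excluded``.
    """
    tumor = np.asarray(tumor, float)
    normal = np.asarray(normal, float)
    if tumor.shape != normal.shape:
        raise ValueError("paired vectors must have equal length")
    keep = (tumor > 0) & (normal > 0) & np.isfinite(tumor) & np.isfinite(normal)
    n_excluded = int((~keep).sum())
    tumor, normal = tumor[keep], normal[keep]
    if len(tumor) < 2:
        raise ValueError("need at least 2 valid pairs")
    t, p = _safe_rel_ttest(np.log(tumor), np.log(normal))
    nt, mt, st, mdt, rt = _describe(tumor)
    nn, mn, sn, mdn, rn = _describe(normal)
    return StatResult(
        test="paired t-test (log rCBV)", groups=labels, n=(nt, nn),
        means=(mt, mn), sems=(st, sn), medians=(mdt, mdn), ranges=(rt, rn),
        t=t, p=p, transform="log", n_excluded=n_excluded)


def group_compare(values: Sequence[float], group_labels: Sequence,
                  paired: bool = False, log_transform: bool = True,
                  test_name: Optional[str] = None) -> StatResult:
    """Two-group comparison (unpaired t-test by default).

    With ``log_transform`` the test runs on ln(values) - used for rCBV;
    tumor sizes are compared on the raw scale (``log_transform=False``).
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels)
    names = [str(g) for g in pd.unique(group_labels)]
    if len(names) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(names)}")
    a = values[group_labels == pd.unique(group_labels)[0]]
    b = values[group_labels == pd.unique(group_labels)[1]]
    n_excluded = 0
    if log_transform:
        n_excluded = int((a <= 0).sum() + (b <= 0).sum())
        a, b = a[a > 0], b[b > 0]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    ta, tb = (np.log(a), np.log(b)) if log_transform else (a, b)
    if paired:
        if len(ta) != len(tb):
            raise ValueError("paired comparison needs equal group sizes")
        t, p = _safe_rel_ttest(ta, tb)
    else:
        t, p = sps.ttest_ind(ta, tb)
    na, ma, sa, mda, ra = _describe(a)
    nb, mb, sb, mdb, rb = _describe(b)
    return StatResult(
        test=test_name or ("paired" if paired else "unpaired") + " t-test",
        groups=tuple(names), n=(na, nb), means=(ma, mb), sems=(sa, sb),
        medians=(mda, mdb), ranges=(ra, rb), t=float(t), p=float(p),
        transform="log" if log_transform else "raw", n_excluded=n_excluded)


def correlate_size_rcbv(areas: Sequence[float], rcbvs: Sequence[float],
                        group_labels: Sequence) -> Dict[str, float]:
    """Per-group R^2 of an ordinary least-squares fit of rCBV on area.

    Degenerate groups (zero variance in area) get NaN; a constant rCBV
    vector gives R^2 = 0 (no variance to explain).
    """
    areas = np.asarray(areas, float)
    rcbvs = np.asarray(rcbvs, float)
    group_labels = np.asarray(group_labels)
    out: Dict[str, float] = {}
    for g in pd.unique(group_labels):
        sel = group_labels == g
        x, y = areas[sel], rcbvs[sel]
        if len(x) < 3:
            raise ValueError(f"group {g!r} needs n >= 3")
        if np.var(x) == 0:
            out[str(g)] = float("nan")
        elif np.var(y) == 0:
            out[str(g)] = 0.0
        else:
            res = sps.linregress(x, y)
            out[str(g)] = float(res.rvalue ** 2)
    return out


def longitudinal_report(tracks: pd.DataFrame) -> Dict[str, StatResult]:
    """Paired tests on tracked lesions with rCBV at two weeks.

    ``tracks`` needs columns ``rcbv_early``, ``rcbv_late``, ``normal_early``,
    ``normal_late``.  Tracks missing any value are excluded.  Returns paired
    log-scale tests: tumor late vs early, and tumor vs contralateral at each
    week.
    """
    cols = ["rcbv_early", "rcbv_late", "normal_early", "normal_late"]
    missing = [c for c in cols if c not in tracks.columns]
    if missing:
        raise ValueError(f"tracks table missing columns {missing}")
    ok = tracks[cols].notna().all(axis=1) & (tracks[cols] > 0).all(axis=1)
    t = tracks[ok]
    if len(t) < 2:
        raise ValueError("need at least 2 complete tracks")
    return {
        "late_tumor_vs_normal": paired_test_rcbv(
            t["rcbv_late"], t["normal_late"],
            labels=("tumor_late", "normal_late")),
        "early_tumor_vs_normal": paired_test_rcbv(
            t["rcbv_early"], t["normal_early"],
            labels=("tumor_early", "normal_early")),
        "tumor_late_vs_early": paired_test_rcbv(
            t["rcbv_late"], t["rcbv_early"],
            labels=("tumor_late", "tumor_early")),
    }


def holm_correction(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def render_report(cohort: pd.DataFrame,
                  mvd: Optional[pd.DataFrame] = None) -> str:
    """Render a markdown summary of the cohort analyses.

    Expects the per-lesion cohort table (columns ``rcbv``, ``normal_rcbv``,
    ``area_mm2``, ``enh_class``, ``region_name``, ``animal``, ``week``).
    """
    lines = ["# Cohort report", ""]
    n = len(cohort)
    lines.append(f"Lesions: {n} across {cohort['animal'].nunique()} animals.")
    enh = cohort["enh_class"].isin(["partial", "full"])
    lines.append(f"Contrast-enhancing: {enh.sum()} ({100 * enh.mean():.1f}%).")
    lines.append("")
    lines.append("## Regional distribution")
    for name, frac in cohort["region_name"].value_counts(normalize=True).items():
        lines.append(f"- {name}: {100 * frac:.1f}%")
    lines.append("")
    measured = cohort.dropna(subset=["rcbv", "normal_rcbv"])
    if len(measured) >= 2:
        res = paired_test_rcbv(measured["rcbv"], measured["normal_rcbv"])
        lines += ["## rCBV: tumor vs contralateral normal", res.summary(), ""]
        groups = measured["enh_class"].isin(["partial", "full"]).map(
            {True: "permeable", False: "non_permeable"})
        if groups.nunique() == 2 and groups.value_counts().min() >= 3:
            gres = group_compare(measured["rcbv"], groups,
                                 test_name="permeable vs non-permeable (rCBV)")
            sres = group_compare(measured["area_mm2"], groups, log_transform=False,
                                 test_name="permeable vs non-permeable (size)")
            r2 = correlate_size_rcbv(measured["area_mm2"], measured["rcbv"], groups)
            lines += ["## Permeability groups", gres.summary(), sres.summary(),
                      "R^2 (rCBV vs size): " +
                      ", ".join(f"{k}={v:.3f}" for k, v in r2.items()), ""]
    if mvd is not None and len(mvd):
        lines.append("## Microvascular density")
        for cls, sub in mvd.groupby("tissue_class"):
            lines.append(f"- {cls}: {sub['mvd_per_mm2'].mean():.0f}"
                         f"±{sub['mvd_per_mm2'].std(ddof=1):.0f} /mm^2"
                         f" (n={len(sub)} fields)")
        lines.append("")
    lines.append("Note: lesions are pooled across animals; within-animal "
                 "correlation is not modeled.")
    return "\n".join(lines) + "\n"
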