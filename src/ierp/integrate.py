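"""Cross-session integration of cluster-test results.

Statistical testing is strictly within-session (electrode coverage is
not comparable across subjects); sessions are combined only by counting:
for each subregion and timepoint, how many sessions show a significant
cluster covering that timepoint, which count ranges are shaded
(light: >= 6 sessions, dark: >= 10), and per-subregion summary rows
(number of significant clusters pooled over sessions, mean and SD of
their p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterTestResult


def _check_axes(results: list[ClusterTestResult]) -> np.ndarray:
    if not results:
        raise ValueError("need at least one session result")
    axis = results[0].rel_time_axis
    for r in results[1:]:
        if len(r.rel_time_axis) != len(axis) or not np.allclose(
            r.rel_time_axis, axis
        ):
            raise ValueError("sessions do not share a relative time axis")
    return axis


def significance_counts(results: list[ClusterTestResult]) -> np.ndarray:
    """Per-timepoint count of sessions with a significant cluster there.

    A session counts at timepoint t when t lies inside the extent of at
    least one of its significant clusters.
    """
    axis = _check_axes(results)
    counts = np.zeros(len(axis), dtype=int)
    for r in results:
        covered = np.zeros(len(axis), dtype=bool)
        for c in r.significant_clusters:
            covered[c.start_idx : c.end_idx + 1] = True
        counts += covered
    return counts


@dataclass
class ShadingInterval:
    t_start_ms: float
    t_end_ms: float
    level: str  # "light" or "dark"


def shading_intervals(
    counts: np.ndarray,
    rel_time_axis: np.ndarray,
    n_light: int = 6,
    n_dark: int = 10,
) -> list[ShadingInterval]:
    """Maximal runs where the session count reaches the shading thresholds.

    Light intervals mark runs with count >= n_light, dark intervals runs
    with count >= n_dark; with n_light <= n_dark every dark interval is
    nested inside a light one.
    """
    out: list[ShadingInterval] = []
    for level, thr in (("light", n_light), ("dark", n_dark)):
        above = np.asarray(counts) >= thr
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                out.append(
                    ShadingInterval(
                        t_start_ms=float(rel_time_axis[i] * 1000.0),
                        t_end_ms=float(rel_time_axis[j] * 1000.0),
                        level=level,
                    )
                )
                i = j + 1
            else:
                i += 1
    return out


def cluster_summary_table(
    results_by_region: dict[str, list[ClusterTestResult]],
    round_decimals: int = 3,
) -> pd.DataFrame:
    """Per-subregion statistics of significant clusters pooled over sessions.

    Emits one row per subregion with the cluster count and the mean and SD
    (population convention, ddof 0) of the pooled p-values, rounded for
    reporting.  Subregions with no significant cluster get count 0 and
    empty statistics.
    """
    rows = []
    for region, results in results_by_region.items():
        ps = [
            c.p_value for r in results for c in r.significant_clusters
        ]
        if ps:
            rows.append(
                {
                    "subregion": region,
                    "n_clusters": len(ps),
                    "mean_p": round(float(np.mean(ps)), round_decimals),
                    "sd_p": round(float(np.std(ps)), round_decimals),
                }
            )
        else:
            rows.append(
                {"subregion": region, "n_clusters": 0,
                 "mean_p": np.nan, "sd_p": np.nan}
            )
    return pd.DataFrame(rows, columns=["subregion", "n_clusters", "mean_p", "sd_p"])


@dataclass
class IntegrationResult:
    """Study-level integration for one condition pair."""

    condition_a: str
    condition_b: str
    n_sessions: int
    rel_time_axis: np.ndarray
    counts: dict[str, np.ndarray]  # per subregion
    shading: dict[str, list[ShadingInterval]]
    summary: pd.DataFrame

    def counts_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts)
        df.insert(0, "time_ms", self.rel_time_axis * 1000.0)
        return df

    def plot_counts(self, region: str, ax=None):
        """Sessions-significant count vs time for one subregion."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.rel_time_axis * 1000.0
        ax.plot(t, self.counts[region], color="purple")
        ax.set_xlabel("time relative to marker (ms)")
        ax.set_ylabel("sessions significant")
        ax.set_ylim(0, self.n_sessions)
        ax.set_title(f"{region}: {self.condition_a} vs {self.condition_b}")
        return ax


def integrate_sessions(
    session_results: list[dict[str, ClusterTestResult]],
    condition_a: str,
    condition_b: str,
    n_light: int = 6,
    n_dark: int = 10,
) -> IntegrationResult:
    """Combine per-session, per-subregion test results into one report."""
    if not session_results:
        raise ValueError("need at least one session")
    regions: list[str] = []
    for s in session_results:
        for r in s:
            if r not in regions:
                regions.append(r)
    counts: dict[str, np.ndarray] = {}
    shading: dict[str, list[ShadingInterval]] = {}
    by_region: dict[str, list[ClusterTestResult]] = {}
    axis = None
    for region in regions:
        results = [s[region] for s in session_results if region in s]
        by_region[region] = results
        axis = _check_axes(results)
        counts[region] = significance_counts(results)
        shading[region] = shading_intervals(counts[region], axis, n_light, n_dark)
    return IntegrationResult(
        condition_a=condition_a,
        condition_b=condition_b,
        n_sessions=len(session_results),
        rel_time_axis=axis,
        counts=counts,
        shading=shading,
        summary=cluster_summary_table(by_region),
    )
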