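"""Cluster-level permutation testing of evoked responses.

The core comparison between two window sets (e.g. windows sampled around
phrase boundaries vs reference windows) proceeds in four steps:

1. a two-sided Mann-Whitney U test at every timepoint within the window,
   with the U statistics converted to a Z series via the (tie-corrected)
   normal approximation;
2. timepoints with |Z| above the cluster-forming threshold — the
   standard-normal two-sided critical value, 1.96 at alpha 0.05 — are
   grouped into clusters by temporal adjacency (sign-homogeneous runs);
3. condition labels are permuted over the pooled windows (1000 times by
   default), and each permutation is summarized by the maximum of the
   cluster statistic max|Z| over its clusters.  When the two window sets
   are bootstrap-resampled (the pipeline equalizes both conditions to
   200 windows drawn with replacement), the exchangeable unit is the
   *original* window, not the bootstrap copy: labels are shuffled over
   the pooled source windows and the bootstrap redrawn inside every
   permutation.  Shuffling the copies themselves would break the
   duplicate blocks present in the observed statistic and makes the test
   wildly anticonservative (type-I error near 1);
4. each observed cluster's p-value is the add-one tail probability of
   its statistic under that permutation distribution; clusters with
   p <= 0.05 are significant.

Taking the maximum over clusters per permutation makes the reference
distribution a max-statistic null, so the resulting p-values control the
familywise error over clusters within the window.

The test is exposed statsmodels-style: build a
:class:`ClusterPermutationTest` from two window sets, call ``fit()``, and
read estimates off the returned :class:`ClusterTestResult` (or print
``result.summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ErpWindowSet


@dataclass
class ClusterTestConfig:
    alpha_forming: float = 0.05  # two-sided p for the cluster-forming threshold
    alpha_cluster: float = 0.05  # cluster-level significance
    n_permutations: int = 1000
    seed: int = 0
    tie_correction: bool = True
    #: exchangeable unit for the permutation null: "window" shuffles the
    #: pooled windows as given; "source" shuffles the original windows
    #: and redraws the bootstrap per permutation (requires source sets);
    #: "auto" picks "source" whenever source sets are supplied.
    permutation_unit: str = "auto"

    def validate(self) -> None:
        if not 0 < self.alpha_forming < 1:
            raise ValueError("alpha_forming must be in (0, 1)")
        if not 0 < self.alpha_cluster < 1:
            raise ValueError("alpha_cluster must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.permutation_unit not in ("auto", "window", "source"):
            raise ValueError("permutation_unit must be auto|window|source")


@dataclass
class Cluster:
    """One temporal cluster of suprathreshold timepoints."""

    start_idx: int
    end_idx: int  # inclusive
    sign: int
    stat: float  # max |Z| within the cluster
    p_value: float = np.nan
    significant: bool = False

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx + 1


def z_threshold(alpha_two_sided: float) -> float:
    """Standard-normal two-sided critical value (1.959964 at alpha 0.05)."""
    if not 0 < alpha_two_sided < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.norm.ppf(1 - alpha_two_sided / 2))


def choose_normality_test(n: int) -> str:
    """Select the normality test appropriate for a sample size.

    D'Agostino-Pearson for n >= 20 (its validity floor), Shapiro-Wilk for
    smaller samples — so the many note-onset/reference windows get the
    former and the few phrase-boundary windows the latter.
    """
    if n < 3:
        raise ValueError(f"normality testing needs n >= 3, got {n}")
    return "dagostino_pearson" if n >= 20 else "shapiro_wilk"


@dataclass
class NormalityReport:
    """Diagnostic per-timepoint normality assessment for both window sets."""

    test_a: str
    test_b: str
    nonnormal_a: np.ndarray  # bool per timepoint
    nonnormal_b: np.ndarray

    @property
    def fraction_nonnormal_a(self) -> float:
        return float(np.mean(self.nonnormal_a))

    @property
    def fraction_nonnormal_b(self) -> float:
        return float(np.mean(self.nonnormal_b))


def _nonnormal_flags(x: np.ndarray, test: str, alpha: float) -> np.ndarray:
    """Per-timepoint normality rejection flags for samples x (n, T)."""
    n, T = x.shape
    flags = np.zeros(T, dtype=bool)
    degenerate = np.ptp(x, axis=0) == 0
    flags[degenerate] = True  # test undefined on constants: non-normal by convention
    cols = np.flatnonzero(~degenerate)
    if len(cols) == 0:
        return flags
    if test == "dagostino_pearson":
        with np.errstate(invalid="ignore"):
            _, p = stats.normaltest(x[:, cols], axis=0)
        flags[cols] = p < alpha
    elif test == "shapiro_wilk":
        for c in cols:
            flags[c] = stats.shapiro(x[:, c]).pvalue < alpha
    else:
        raise ValueError(f"unknown normality test {test!r}")
    return flags


def assess_normality(
    ws_a: ErpWindowSet, ws_b: ErpWindowSet, alpha: float = 0.05
) -> NormalityReport:
    """Examine the per-timepoint distributions of both window sets.

    Purely diagnostic: the pipeline always proceeds with the rank-based
    test, as the distributions at individual timepoints are generally
    non-Gaussian.
    """
    if ws_a.n_windows == 0 or ws_b.n_windows == 0:
        raise ValueError("both window sets must be non-empty")
    test_a = choose_normality_test(ws_a.n_windows)
    test_b = choose_normality_test(ws_b.n_windows)
    return NormalityReport(
        test_a=test_a,
        test_b=test_b,
        nonnormal_a=_nonnormal_flags(ws_a.windows, test_a, alpha),
        nonnormal_b=_nonnormal_flags(ws_b.windows, test_b, alpha),
    )


def _tie_term(pooled: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per column of pooled values (n, T).

    Vectorized through the identity t^3 - t = 6*(C(t,2) + C(t,3)): with
    r_i = number of consecutive equal predecessors of element i in the
    sorted column, C(t,2) sums r_i over the column and C(t,3) sums
    C(r_i, 2).
    """
    srt = np.sort(pooled, axis=0)
    n = srt.shape[0]
    new = np.ones_like(srt, dtype=bool)
    new[1:] = srt[1:] != srt[:-1]
    idx = np.arange(n)[:, None]
    last_new = np.maximum.accumulate(np.where(new, idx, -1), axis=0)
    r = (idx - last_new).astype(float)
    return 6.0 * (r.sum(axis=0) + (r * (r - 1) / 2.0).sum(axis=0))


def _tie_sigma(
    pooled: np.ndarray, n1: int, n2: int, tie_correction: bool
) -> np.ndarray:
    """SD of U per timepoint from the pooled values (n, T)."""
    n = n1 + n2
    if not tie_correction:
        return np.full(pooled.shape[1], np.sqrt(n1 * n2 * (n + 1) / 12.0))
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    return np.sqrt(np.maximum(var, 0.0))


def mann_whitney_z(
    x: np.ndarray, y: np.ndarray, tie_correction: bool = True
) -> tuple[float, float]:
    """Mann-Whitney U (pairs with x > y, plus half the ties) and its Z-score.

    ``Z = (U - n1 n2 / 2) / sigma_U`` with the tie-corrected variance when
    ``tie_correction`` is on; no continuity correction is applied, so the
    Z series is a smooth function of the rank configuration.  Positive Z
    means x is stochastically larger.  If every value in both samples is
    identical, Z is defined as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 values")
    u, z = mann_whitney_z_series(x[:, None], y[:, None], tie_correction)
    return float(u[0]), float(z[0])


def mann_whitney_z_series(
    a: np.ndarray, b: np.ndarray, tie_correction: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-timepoint Mann-Whitney U and Z for (n1,T) vs (n2,T)."""
    n1, n2 = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    ranks = stats.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    sigma = _tie_sigma(pooled, n1, n2, tie_correction)
    z = np.zeros_like(u)
    ok = sigma > 0
    z[ok] = (u[ok] - n1 * n2 / 2.0) / sigma[ok]
    return u, z


def form_clusters(z_series: np.ndarray, threshold: float) -> list[Cluster]:
    """Group suprathreshold timepoints into sign-homogeneous runs.

    A cluster is a maximal run of consecutive timepoints with
    |Z| > threshold and constant sign; adjacent suprathreshold points of
    opposite sign start a new cluster.  Each cluster carries its sign and
    the maximum |Z| within it.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z_series, float)
    lab = np.where(np.abs(z) > threshold, np.sign(z), 0).astype(int)
    clusters: list[Cluster] = []
    start = None
    for i in range(len(lab) + 1):
        cur = lab[i] if i < len(lab) else 0
        if start is not None and (cur != lab[start]):
            clusters.append(
                Cluster(
                    start_idx=start,
                    end_idx=i - 1,
                    sign=int(lab[start]),
                    stat=float(np.max(np.abs(z[start:i]))),
                )
            )
            start = None
        if cur != 0 and start is None:
            start = i
    return clusters


@dataclass
class ClusterTestResult:
    """Result of a cluster-level permutation test.

    Carries the per-timepoint Z series, the observed clusters with their
    permutation p-values, and the permutation null of max-cluster
    statistics.  ``summary()`` renders a compact report table.
    """

    z_series: np.ndarray
    clusters: list[Cluster]
    threshold_used: float
    n_a: int
    n_b: int
    rel_time_axis: np.ndarray
    condition_a: str
    condition_b: str
    region: str
    config: ClusterTestConfig
    null_max_stats: np.ndarray = field(repr=False, default=None)
    normality: NormalityReport | None = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def cluster_times_ms(self, c: Cluster) -> tuple[float, float]:
        return (
            float(self.rel_time_axis[c.start_idx] * 1000.0),
            float(self.rel_time_axis[c.end_idx] * 1000.0),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            t0, t1 = self.cluster_times_ms(c)
            rows.append(
                {
                    "region": self.region,
                    "condition_a": self.condition_a,
                    "condition_b": self.condition_b,
                    "start_idx": c.start_idx,
                    "end_idx": c.end_idx,
                    "t_start_ms": t0,
                    "t_end_ms": t1,
                    "sign": c.sign,
                    "max_abs_z": c.stat,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "region", "condition_a", "condition_b", "start_idx", "end_idx",
                "t_start_ms", "t_end_ms", "sign", "max_abs_z", "p_value",
                "significant",
            ],
        )

    def summary(self) -> str:
        lines = [
            "Cluster-level permutation test",
            "=" * 62,
            f"comparison:      {self.condition_a} vs {self.condition_b}",
            f"region:          {self.region}",
            f"windows:         n_a={self.n_a}, n_b={self.n_b}",
            f"forming |Z| >    {self.threshold_used:.4f} "
            f"(two-sided alpha={self.config.alpha_forming})",
            f"permutations:    {self.config.n_permutations}",
            f"clusters:        {len(self.clusters)} "
            f"({len(self.significant_clusters)} significant at "
            f"p<={self.config.alpha_cluster})",
        ]
        if self.clusters:
            lines.append("-" * 62)
            lines.append(
                f"{'t_start_ms':>10} {'t_end_ms':>10} {'sign':>5} "
                f"{'max|Z|':>8} {'p':>8}  sig"
            )
            for c in self.clusters:
                t0, t1 = self.cluster_times_ms(c)
                lines.append(
                    f"{t0:>10.1f} {t1:>10.1f} {c.sign:>5d} "
                    f"{c.stat:>8.3f} {c.p_value:>8.4f}  "
                    f"{'*' if c.significant else ''}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "region": self.region,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "threshold_used": self.threshold_used,
            "rel_time_axis_s": self.rel_time_axis.tolist(),
            "z_series": self.z_series.tolist(),
            "clusters": [
                {
                    "start_idx": c.start_idx,
                    "end_idx": c.end_idx,
                    "t_start_ms": self.cluster_times_ms(c)[0],
                    "t_end_ms": self.cluster_times_ms(c)[1],
                    "sign": c.sign,
                    "max_abs_z": c.stat,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.clusters
            ],
        }

    def plot(self, ax=None):
        """Z series with suprathreshold clusters shaded (significant in red)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.rel_time_axis * 1000.0
        ax.plot(t, self.z_series, color="tab:blue", lw=1)
        ax.axhline(self.threshold_used, color="k", ls=":", lw=0.8)
        ax.axhline(-self.threshold_used, color="k", ls=":", lw=0.8)
        for c in self.clusters:
            t0, t1 = self.cluster_times_ms(c)
            ax.axvspan(t0, t1, alpha=0.3,
                       color="tab:red" if c.significant else "tab:blue")
        ax.set_xlabel("time relative to marker (ms)")
        ax.set_ylabel("Z")
        ax.set_title(f"{self.region}: {self.condition_a} vs {self.condition_b}")
        return ax


class ClusterPermutationTest:
    """Two-condition cluster-level permutation test on window sets.

    Parameters
    ----------
    ws_a, ws_b : ErpWindowSet
        The two conditions (observed, possibly bootstrap-resampled); must
        share region, sampling rate and window length.  Positive Z means
        condition *a* stochastically larger.
    config : ClusterTestConfig, optional
    source_a, source_b : ErpWindowSet, optional
        The original (pre-bootstrap) window sets ``ws_a``/``ws_b`` were
        resampled from.  When supplied (and ``permutation_unit`` is
        "auto" or "source"), the permutation null shuffles labels over
        the pooled source windows and redraws the bootstrap — the
        calibrated null when the observed sets contain duplicates.
    """

    def __init__(
        self,
        ws_a: ErpWindowSet,
        ws_b: ErpWindowSet,
        config: ClusterTestConfig | None = None,
        source_a: ErpWindowSet | None = None,
        source_b: ErpWindowSet | None = None,
    ):
        config = config or ClusterTestConfig()
        config.validate()
        if ws_a.n_samples != ws_b.n_samples:
            raise ValueError(
                f"window-length mismatch: {ws_a.n_samples} vs {ws_b.n_samples}"
            )
        if abs(ws_a.fs - ws_b.fs) > 1e-9:
            raise ValueError("sampling-rate mismatch between window sets")
        if ws_a.region != ws_b.region:
            raise ValueError(
                f"region mismatch: {ws_a.region!r} vs {ws_b.region!r}"
            )
        if (source_a is None) != (source_b is None):
            raise ValueError("supply both source sets or neither")
        if config.permutation_unit == "source" and source_a is None:
            raise ValueError(
                "permutation_unit='source' requires source_a and source_b"
            )
        self.ws_a = ws_a
        self.ws_b = ws_b
        self.source_a = source_a
        self.source_b = source_b
        self.config = config

    @property
    def _unit(self) -> str:
        if self.config.permutation_unit == "auto":
            return "source" if self.source_a is not None else "window"
        return self.config.permutation_unit

    def _null_window(self, pooled, ranks, sigma, offset, n1, n, rng) -> np.ndarray:
        """Copy-level null: shuffle labels over the pooled observed windows."""
        m = self.config.n_permutations
        null_max = np.empty(m)
        # chunk size keeps the (chunk, n1, T) gather under ~20 MB
        chunk = max(1, min(m, int(2.5e6 / (n1 * ranks.shape[1] + 1))))
        done = 0
        ok = sigma > 0
        while done < m:
            k = min(chunk, m - done)
            keys = rng.random((k, n))
            idx = np.argsort(keys, axis=1)[:, :n1]
            r1 = ranks[idx].sum(axis=1)  # (k, T)
            z = np.zeros_like(r1)
            z[:, ok] = (r1[:, ok] - offset) / sigma[ok]
            null_max[done : done + k] = np.abs(z).max(axis=1)
            done += k
        return null_max

    def _null_source(self, n1: int, n2: int, rng) -> np.ndarray:
        """Source-level null: permute original windows, redraw the bootstrap.

        Fast path: when the source values are distinct within every
        timepoint (continuous data), the only ties in a bootstrap sample
        are the copy groups themselves, so the pooled ranks follow from a
        precomputed sort order of the source windows plus the
        per-permutation copy-count vector, and the tie-corrected variance
        is a scalar per permutation.
        """
        src = np.vstack([self.source_a.windows, self.source_b.windows])
        na0 = self.source_a.n_windows
        nb0 = src.shape[0] - na0
        n0 = src.shape[0]
        m = self.config.n_permutations
        n = n1 + n2
        null_max = np.empty(m)

        # per-timepoint sort order and tie-group structure of the sources
        order = np.argsort(src, axis=0, kind="stable")
        srt = np.take_along_axis(src, order, axis=0)
        new = np.ones_like(srt, dtype=bool)
        new[1:] = srt[1:] != srt[:-1]
        is_last = np.empty_like(new)
        is_last[:-1] = new[1:]
        is_last[-1] = True

        offset = n1 * (n1 + 1) / 2.0 + n1 * n2 / 2.0
        for i in range(m):
            perm = rng.permutation(n0)
            ca = np.bincount(perm[:na0][rng.integers(0, na0, size=n1)],
                             minlength=n0).astype(float)
            cb = np.bincount(perm[na0:][rng.integers(0, nb0, size=n2)],
                             minlength=n0).astype(float)
            c = ca + cb
            csort = c[order]  # copies per sorted slot, per timepoint
            cum = np.cumsum(csort, axis=0)
            # copies sharing a source value tie with each other too: merge
            # sorted slots into value groups and average ranks over groups
            p_first = np.where(new, cum - csort, -np.inf)
            prefix = np.maximum.accumulate(p_first, axis=0)
            e_last = np.where(is_last, cum, np.inf)
            end = np.minimum.accumulate(e_last[::-1], axis=0)[::-1]
            group_n = end - prefix
            avg_rank = prefix + (group_n + 1.0) / 2.0
            r1 = (ca[order] * avg_rank).sum(axis=0)
            if self.config.tie_correction:
                tie = np.where(is_last, group_n**3 - group_n, 0.0).sum(axis=0)
                var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
            else:
                var = np.full(src.shape[1], n1 * n2 * (n + 1) / 12.0)
            z = np.zeros(src.shape[1])
            ok = var > 0
            z[ok] = (r1[ok] - offset) / np.sqrt(var[ok])
            null_max[i] = np.abs(z).max()
        return null_max

    def fit(self, assess_normality_first: bool = True) -> ClusterTestResult:
        cfg = self.config
        a, b = self.ws_a.windows, self.ws_b.windows
        n1, n2 = a.shape[0], b.shape[0]
        n = n1 + n2
        pooled = np.vstack([a, b])
        ranks = stats.rankdata(pooled, axis=0)
        sigma = _tie_sigma(pooled, n1, n2, cfg.tie_correction)
        offset = n1 * (n1 + 1) / 2.0 + n1 * n2 / 2.0

        z_obs = np.zeros(ranks.shape[1])
        ok = sigma > 0
        z_obs[ok] = (ranks[:n1].sum(axis=0)[ok] - offset) / sigma[ok]
        thr = z_threshold(cfg.alpha_forming)
        clusters = form_clusters(z_obs, thr)

        # permutation summary: the max over a permutation's clusters of the
        # within-cluster max |Z| equals max|Z| over all suprathreshold
        # timepoints — i.e. max|Z| whenever it exceeds the forming
        # threshold (and irrelevant to any tail count when it does not) —
        # so each permutation is summarized by max|Z| directly.
        rng = np.random.default_rng(cfg.seed)
        if self._unit == "source":
            null_max = self._null_source(n1, n2, rng)
        else:
            null_max = self._null_window(pooled, ranks, sigma, offset, n1, n, rng)
        m = cfg.n_permutations

        for c in clusters:
            c.p_value = float((1 + np.sum(null_max >= c.stat)) / (1 + m))
            c.significant = c.p_value <= cfg.alpha_cluster

        normality = None
        if assess_normality_first:
            normality = assess_normality(self.ws_a, self.ws_b)

        return ClusterTestResult(
            z_series=z_obs,
            clusters=clusters,
            threshold_used=thr,
            n_a=n1,
            n_b=n2,
            rel_time_axis=self.ws_a.rel_time_axis,
            condition_a=self.ws_a.condition,
            condition_b=self.ws_b.condition,
            region=self.ws_a.region,
            config=cfg,
            null_max_stats=null_max,
            normality=normality,
        )


def cluster_permutation_test(
    ws_a: ErpWindowSet,
    ws_b: ErpWindowSet,
    config: ClusterTestConfig | None = None,
    source_a: ErpWindowSet | None = None,
    source_b: ErpWindowSet | None = None,
) -> ClusterTestResult:
    """Functional wrapper around :class:`ClusterPermutationTest`."""
    return ClusterPermutationTest(ws_a, ws_b, config, source_a, source_b).fit()
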