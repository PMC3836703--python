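"""The full miR-gene association screen.

For every miR-gene pair in the universe the screen fits the greedy
partition (Group 1 = patients whose joint expression sustains a strong
correlation, Group 2 = complement), applies the validity criterion
(significantly negative correlation in Group 1, none in Group 2),
compares survival between the groups with the log-rank test, controls
the family-wise error over all valid pairs by Bonferroni, rejects pairs
whose stratification is explained by an expression-level shift of the
gene or the miR (abundance filter), and annotates binding-site support
from a user-supplied prediction table. Survival-label permutation gives
an empirical FDR for the discovery count, and a per-pair sensitivity
analysis measures how much the greedy outcome depends on its random
seed triple.

The model/results surface follows the statsmodels convention:
``MirGeneScreen(data, config).fit()`` returns :class:`ScreenResults`
carrying per-pair statistics, a ``summary()``, and the follow-up
analyses as methods. The underlying stage functions (``scan_pairs``,
``apply_family_correction``, ...) are importable directly.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .io import AlignedDataset, BindingPredictionTable, ClinicalTable
from .partition import (
    Partition,
    ValidityFlags,
    all_triples,
    best_partition,
    greedy_partition,
    pair_validity,
)
from .stats import LogrankResult, bonferroni_threshold, logrank_test, ranksum_test

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PairResult",
    "FDRResult",
    "SensitivityResult",
    "MirGeneScreen",
    "ScreenResults",
    "scan_pairs",
    "apply_family_correction",
    "abundance_filter",
    "annotate_binding",
    "permutation_fdr",
    "sensitivity_analysis",
    "covariate_balance",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Screen-wide tuning parameters.

    alpha_corr
        Within-group correlation significance level (Group 1 must fall
        below it, Group 2 must not).
    alpha_family
        Family-wise error rate for the Bonferroni-corrected log-rank
        p-values, divided by the number of valid pairs.
    alpha_filter
        Level of the two-group rank-sum abundance filter.
    min_group_size
        Smallest admissible patient group; survival comparison on tiny
        groups is meaningless.
    n_restarts
        Independent seed triples per pair for the greedy search.
    n_fdr_iterations
        Survival-label permutations for the empirical FDR.
    correlation_method
        "pearson" (default) or "spearman".
    admission
        Greedy admission criterion: "significance" (default — a patient
        is excluded only when it would weaken both the correlation and
        its significance) or "correlation" (the pure |r| ratchet); see
        :func:`mirstrat.partition.greedy_partition`.
    pair_universe
        Optional explicit list of (mir_id, gene_id) pairs; default is
        the full cross product.
    max_passes
        Greedy passes per restart (1 = single scan; more enables
        re-scanning previously rejected patients until stable).
    filter_alternative
        "two-sided" (default) or a one-sided alternative for the
        abundance rank-sum test.
    """

    alpha_corr: float = 0.05
    alpha_family: float = 0.05
    alpha_filter: float = 0.05
    min_group_size: int = 10
    n_restarts: int = 10
    n_fdr_iterations: int = 1000
    seed: int = 0
    correlation_method: str = "pearson"
    admission: str = "significance"
    pair_universe: tuple[tuple[str, str], ...] | None = None
    max_passes: int = 1
    filter_alternative: str = "two-sided"

    def __post_init__(self) -> None:
        for name in ("alpha_corr", "alpha_family", "alpha_filter"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("min_group_size", "n_restarts", "n_fdr_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")
        if self.admission not in ("correlation", "significance"):
            raise ValueError("admission must be 'correlation' or 'significance'")
        if self.pair_universe is not None:
            object.__setattr__(
                self,
                "pair_universe",
                tuple((str(m), str(g)) for m, g in self.pair_universe),
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["pair_universe"] is not None:
            d["pair_universe"] = [list(p) for p in d["pair_universe"]]
        return d


@dataclass
class PairResult:
    """Everything the screen knows about one miR-gene pair."""

    mir_id: str
    gene_id: str
    partition: Partition | None = None
    validity: ValidityFlags | None = None
    logrank: LogrankResult | None = None
    bonferroni_pass: bool = False
    abundance_pass: bool | None = None
    abundance_p_gene: float | None = None
    abundance_p_mir: float | None = None
    binding_tools: list[str] | None = None  # None = no prediction table supplied
    skipped: bool = False
    skip_reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.validity is not None and self.validity.valid

    @property
    def final_pass(self) -> bool:
        binding_ok = self.binding_tools is None or len(self.binding_tools) > 0
        return (
            self.valid
            and self.bonferroni_pass
            and self.abundance_pass is True
            and binding_ok
        )


@dataclass(frozen=True)
class FDRResult:
    """Bonferroni-survivor counts under survival-label permutation."""

    counts: np.ndarray
    observed_count: int
    n_iterations: int
    m_valid: int
    threshold: float

    @property
    def max_count(self) -> int:
        return int(self.counts.max(initial=0))

    @property
    def empirical_fdr_bound(self) -> float:
        """Add-one empirical probability of a permuted discovery count
        at least as large as the observed one."""
        exceed = int(np.sum(self.counts >= self.observed_count))
        return (1 + exceed) / (self.n_iterations + 1)


@dataclass(frozen=True)
class SensitivityResult:
    """Dependence of the greedy outcome on the initial seed triple."""

    mir_id: str
    gene_id: str
    abs_r: np.ndarray
    n_triples_evaluated: int

    @property
    def mean(self) -> float:
        return float(self.abs_r.mean())

    @property
    def std(self) -> float:
        return float(self.abs_r.std(ddof=0))

    @property
    def cv(self) -> float:
        m = self.mean
        return float(self.std / m) if m > 0 else float("inf")


def _pair_seed(seed: int, mir_id: str, gene_id: str) -> np.random.SeedSequence:
    """Stable per-pair seed: independent of scan order and universe subsetting."""
    h = zlib.crc32(f"{mir_id}\t{gene_id}".encode())
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h])


def _universe(data: AlignedDataset, config: PipelineConfig):
    if config.pair_universe is not None:
        return list(config.pair_universe)
    return [
        (m, g) for g in data.gene_expr.feature_ids for m in data.mir_expr.feature_ids
    ]


def scan_pairs(data: AlignedDataset, config: PipelineConfig) -> list[PairResult]:
    """Fit the greedy partition and validity criterion for every pair.

    Pairs whose expression vector is constant are recorded with a skip
    flag, never dropped silently. The log-rank test is computed only for
    valid pairs. Deterministic given ``config.seed``.
    """
    pairs = _universe(data, config)
    if not pairs:
        raise ValueError("empty pair universe")
    if config.pair_universe is not None:
        known_m = set(data.mir_expr.feature_ids)
        known_g = set(data.gene_expr.feature_ids)
        missing = [(m, g) for m, g in pairs if m not in known_m or g not in known_g]
        if missing:
            raise ValueError(f"pair universe references unknown features: {missing[:5]}")
    times = data.clinical.times()
    events = data.clinical.events()
    results: list[PairResult] = []
    for i, (mir_id, gene_id) in enumerate(pairs):
        if i and i % 1000 == 0:
            logger.info("scanned %d / %d pairs", i, len(pairs))
        mir_vec = data.mir_expr.row(mir_id)
        gene_vec = data.gene_expr.row(gene_id)
        res = PairResult(mir_id=mir_id, gene_id=gene_id)
        if np.ptp(mir_vec) == 0 or np.ptp(gene_vec) == 0:
            res.skipped = True
            res.skip_reason = "zero-variance expression vector"
            results.append(res)
            continue
        part = best_partition(
            mir_vec,
            gene_vec,
            n_restarts=config.n_restarts,
            seed=_pair_seed(config.seed, mir_id, gene_id),
            min_group_size=config.min_group_size,
            alpha_corr=config.alpha_corr,
            admission=config.admission,
            max_passes=config.max_passes,
            method=config.correlation_method,
        )
        res.partition = part
        res.validity = pair_validity(part, config.alpha_corr, config.min_group_size)
        if res.validity.valid:
            res.logrank = logrank_test(times, events, part.labels())
        results.append(res)
    logger.info(
        "scan complete: %d pairs, %d valid, %d skipped",
        len(results),
        sum(r.valid for r in results),
        sum(r.skipped for r in results),
    )
    return results


def apply_family_correction(
    results: list[PairResult], alpha_family: float = 0.05
) -> list[PairResult]:
    """Bonferroni over the family of valid (survival-tested) pairs.

    The family size m is the number of valid pairs, so the per-pair
    threshold is ``alpha_family / m``. Updates ``bonferroni_pass`` in
    place and returns the list.
    """
    m = sum(r.valid for r in results)
    if m == 0:
        logger.warning("no valid pairs; Bonferroni correction skipped")
        for r in results:
            r.bonferroni_pass = False
        return results
    thr = bonferroni_threshold(m, alpha_family)
    for r in results:
        r.bonferroni_pass = bool(r.valid and r.logrank is not None and r.logrank.p < thr)
    return results


def abundance_filter(
    results: list[PairResult],
    data: AlignedDataset,
    alpha_filter: float = 0.05,
    alternative: str = "two-sided",
) -> list[PairResult]:
    """Reject stratifications explained by expression level, not correlation.

    For every valid pair the gene's and the miR's values are compared
    Group 1 vs Group 2 with the rank-sum test; the pair passes when
    neither shows a significant level difference (no regulation signal
    can be read off a pair when one of the participants is effectively
    absent from one group).
    """
    for r in results:
        if not r.valid or r.partition is None:
            continue
        g1 = list(r.partition.group1)
        g2 = list(r.partition.group2)
        gene_vec = data.gene_expr.row(r.gene_id)
        mir_vec = data.mir_expr.row(r.mir_id)
        r.abundance_p_gene = ranksum_test(gene_vec[g1], gene_vec[g2], alternative)
        r.abundance_p_mir = ranksum_test(mir_vec[g1], mir_vec[g2], alternative)
        r.abundance_pass = bool(
            r.abundance_p_gene >= alpha_filter and r.abundance_p_mir >= alpha_filter
        )
    return results


def annotate_binding(
    results: list[PairResult], predictions: BindingPredictionTable | None
) -> list[PairResult]:
    """Attach the tools predicting a binding site for each pair.

    Without a prediction table the binding criterion is vacuous and
    pairs stay flagged unannotated (``binding_tools is None``).
    """
    if predictions is None:
        return results
    for r in results:
        r.binding_tools = predictions.tools_for(r.mir_id, r.gene_id)
    return results


def _sorted_survival(times: np.ndarray, events: np.ndarray):
    """Pre-sorted survival layout shared by the vectorised log-rank."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    n = t.size
    new_t = np.empty(n, dtype=bool)
    new_t[0] = True
    new_t[1:] = t[1:] != t[:-1]
    starts = np.flatnonzero(new_t)
    d = np.add.reduceat(e.astype(np.int64), starts)
    keep = d > 0
    return order, e, starts, d, keep, n - starts


def _logrank_chi2_many(labels: np.ndarray, order, e_sorted, starts, d, keep, n_at_risk):
    """Log-rank chi-square for many label rows against one fixed survival.

    ``labels`` is (n_pairs, n_samples) boolean; returns chi2 per row
    (0 where the variance vanishes).
    """
    L = labels[:, order]
    npairs, n = L.shape
    c0 = np.zeros((npairs, n + 1), dtype=np.int64)
    np.cumsum(L, axis=1, out=c0[:, 1:])
    n1_at = L.sum(axis=1)[:, None] - c0[:, starts]
    d1 = np.add.reduceat(L & e_sorted, starts, axis=1)
    d1 = d1[:, keep]
    n1_at = n1_at[:, keep]
    dd = d[keep].astype(float)
    nn = n_at_risk[keep].astype(float)
    frac = n1_at / nn
    o_minus_e = np.sum(d1 - dd * frac, axis=1)
    denom = np.where(nn > 1, nn - 1.0, 1.0)
    var = np.sum(dd * frac * (1.0 - frac) * (nn - dd) / denom, axis=1)
    chi2 = np.zeros(npairs)
    ok = var > 0
    chi2[ok] = o_minus_e[ok] ** 2 / var[ok]
    return chi2


def permutation_fdr(
    results: list[PairResult],
    data: AlignedDataset,
    config: PipelineConfig,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> FDRResult:
    """Empirical FDR by survival-label permutation.

    Each iteration permutes the (time, event) pairs jointly across
    samples, recomputes the log-rank test for every valid pair against
    its *fixed* partition (partitions depend only on expression, not on
    survival), and counts how many pairs would pass the same Bonferroni
    rule. The add-one bound
    ``(1 + #{count >= observed}) / (n_iterations + 1)`` estimates how
    often chance alone produces a discovery set at least as large as the
    observed one.
    """
    n_iterations = config.n_fdr_iterations if n_iterations is None else n_iterations
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(
        np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, 0xFD0])
    )
    valid = [r for r in results if r.valid and r.partition is not None]
    observed = sum(r.bonferroni_pass for r in results)
    m = len(valid)
    if m == 0:
        return FDRResult(
            counts=np.zeros(n_iterations, dtype=int),
            observed_count=observed,
            n_iterations=n_iterations,
            m_valid=0,
            threshold=float("nan"),
        )
    thr = bonferroni_threshold(m, config.alpha_family)
    crit = float(sps.chi2.isf(thr, 1))

    times = data.clinical.times()
    events = data.clinical.events()
    labels = np.stack([r.partition.labels() for r in valid])
    layout = _sorted_survival(times, events)
    order = layout[0]
    counts = np.empty(n_iterations, dtype=int)
    n = times.size
    for it in range(n_iterations):
        perm = rng.permutation(n)
        # permuting survival across samples == relabelling samples: apply
        # the inverse permutation to the group labels instead, so the
        # sorted survival layout is computed once
        inv = np.argsort(perm)
        chi2 = _logrank_chi2_many(labels[:, inv], *layout)
        counts[it] = int(np.sum(chi2 > crit))
    return FDRResult(
        counts=counts,
        observed_count=observed,
        n_iterations=n_iterations,
        m_valid=m,
        threshold=thr,
    )


def sensitivity_analysis(
    mir_vec,
    gene_vec,
    n_triples: int = 100,
    mode: str = "sampled",
    seed: int = 0,
    *,
    exhaustive_cap: int = 50_000,
    mir_id: str = "",
    gene_id: str = "",
    admission: str = "significance",
    method: str = "pearson",
) -> SensitivityResult:
    """Spread of the greedy |r| over initial seed triples.

    Runs :func:`greedy_partition` once per triple (sampled uniformly, or
    every C(n,3) triple in ``exhaustive`` mode when that count does not
    exceed ``exhaustive_cap``) under a fixed scan-order policy: a single
    seeded base permutation of the samples, with each triple's members
    removed. A small standard deviation relative to the mean indicates
    the outcome does not depend on the arbitrary initial choice.
    """
    x = np.asarray(mir_vec, dtype=float)
    n = x.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5E]))
    base_order = rng.permutation(n)
    if mode == "exhaustive":
        total = n * (n - 1) * (n - 2) // 6
        if total > exhaustive_cap:
            raise ValueError(
                f"exhaustive mode over C({n},3) = {total} triples exceeds the cap "
                f"of {exhaustive_cap}"
            )
        triples = list(all_triples(n))
    elif mode == "sampled":
        if n_triples < 1:
            raise ValueError("n_triples must be >= 1")
        triples = [tuple(rng.choice(n, size=3, replace=False)) for _ in range(n_triples)]
    else:
        raise ValueError("mode must be 'sampled' or 'exhaustive'")

    values = np.empty(len(triples))
    for i, tri in enumerate(triples):
        mask = np.ones(n, dtype=bool)
        mask[list(tri)] = False
        scan_order = base_order[mask[base_order]]
        part = greedy_partition(
            mir_vec, gene_vec, tri, scan_order, admission=admission, method=method
        )
        values[i] = abs(part.corr1.r)
    return SensitivityResult(
        mir_id=mir_id, gene_id=gene_id, abs_r=values, n_triples_evaluated=len(triples)
    )


def covariate_balance(partition: Partition, clinical: ClinicalTable) -> pd.DataFrame:
    """Compare every clinical covariate between the two patient groups.

    Numeric covariates use the rank-sum test, categorical ones the
    chi-square test on the contingency table. Descriptive: no
    multiplicity correction. Constant covariates are skipped with a
    note. Returns one row per covariate (covariate, test, p, note).
    """
    names = clinical.covariate_names
    if not names:
        raise ValueError("clinical table has no covariates")
    lab = partition.labels()
    rows = []
    for name in names:
        col = clinical.table[name]
        if col.nunique(dropna=True) <= 1:
            rows.append((name, "skipped", np.nan, "constant covariate"))
            continue
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            p = ranksum_test(col.to_numpy(dtype=float)[lab], col.to_numpy(dtype=float)[~lab])
            rows.append((name, "rank-sum", p, ""))
        else:
            ct = pd.crosstab(lab, col.to_numpy())
            chi2, p, _, _ = sps.chi2_contingency(ct.to_numpy(), correction=False)
            rows.append((name, "chi-square", float(p), ""))
    return pd.DataFrame(rows, columns=["covariate", "test", "p", "note"])


class MirGeneScreen:
    """Model object: a miR-gene association screen over an aligned cohort.

    Parameters
    ----------
    data : AlignedDataset
        Gene expression, miR expression and clinical survival restricted
        to their common samples (see :func:`mirstrat.io.align_dataset`).
    config : PipelineConfig, optional
    predictions : BindingPredictionTable, optional
        When supplied, the final discovery set additionally requires at
        least one program predicting a binding site for the pair.

    Examples
    --------
    >>> from mirstrat import MirGeneScreen, PipelineConfig
    >>> from mirstrat.simulate import SyntheticSpec, generate
    >>> ds = generate(SyntheticSpec(seed=1))
    >>> res = MirGeneScreen(ds.data, PipelineConfig(seed=1)).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        data: AlignedDataset,
        config: PipelineConfig | None = None,
        predictions: BindingPredictionTable | None = None,
    ):
        self.data = data
        self.config = config or PipelineConfig()
        self.predictions = predictions
        if data.n_samples < 2 * self.config.min_group_size:
            raise ValueError(
                "aligned dataset too small for the configured minimum group size"
            )

    @classmethod
    def from_files(
        cls,
        gene_path,
        mir_path,
        clinical_path,
        prediction_path=None,
        config: PipelineConfig | None = None,
        column_map: dict | None = None,
        strict: bool = False,
    ) -> "MirGeneScreen":
        from .io import (
            align_dataset,
            read_clinical_table,
            read_expression_matrix,
            read_prediction_table,
        )

        config = config or PipelineConfig()
        data = align_dataset(
            read_expression_matrix(gene_path, strict=strict),
            read_expression_matrix(mir_path, strict=strict),
            read_clinical_table(clinical_path, column_map),
            min_group_size=config.min_group_size,
        )
        preds = (
            read_prediction_table(prediction_path) if prediction_path is not None else None
        )
        return cls(data, config, preds)

    def fit(self) -> "ScreenResults":
        """Run the full cascade: scan, Bonferroni, abundance, binding."""
        cfg = self.config
        pairs = scan_pairs(self.data, cfg)
        apply_family_correction(pairs, cfg.alpha_family)
        abundance_filter(pairs, self.data, cfg.alpha_filter, cfg.filter_alternative)
        annotate_binding(pairs, self.predictions)
        return ScreenResults(self, pairs)


class ScreenResults:
    """Fitted screen: per-pair statistics plus the follow-up analyses."""

    def __init__(self, model: MirGeneScreen, pairs: list[PairResult]):
        self.model = model
        self.pairs = pairs

    # -- basic accessors -------------------------------------------------
    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    @property
    def data(self) -> AlignedDataset:
        return self.model.data

    @property
    def final_pairs(self) -> list[PairResult]:
        return [r for r in self.pairs if r.final_pass]

    def get_pair(self, mir_id: str, gene_id: str) -> PairResult:
        for r in self.pairs:
            if r.mir_id == mir_id and r.gene_id == gene_id:
                return r
        raise KeyError(f"pair ({mir_id}, {gene_id}) not in the scanned universe")

    def cascade_counts(self) -> dict[str, int]:
        """Pair counts surviving each successive filter."""
        valid = [r for r in self.pairs if r.valid]
        bonf = [r for r in valid if r.bonferroni_pass]
        abund = [r for r in bonf if r.abundance_pass]
        return {
            "scanned": len(self.pairs),
            "skipped": sum(r.skipped for r in self.pairs),
            "valid": len(valid),
            "bonferroni": len(bonf),
            "abundance": len(abund),
            "final": len(self.final_pairs),
        }

    # -- tabular output --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        sample_ids = np.asarray(self.data.sample_ids)
        rows = []
        for r in self.pairs:
            p = r.partition
            rows.append(
                {
                    "mir_id": r.mir_id,
                    "gene_id": r.gene_id,
                    "skipped": r.skipped,
                    "n1": len(p.group1) if p else 0,
                    "n2": len(p.group2) if p else 0,
                    "r1": p.corr1.r if p else np.nan,
                    "p1": p.corr1.p if p else np.nan,
                    "r2": p.corr2.r if p else np.nan,
                    "p2": p.corr2.p if p else np.nan,
                    "valid": r.valid,
                    "logrank_chi2": r.logrank.chi2 if r.logrank else np.nan,
                    "logrank_p": r.logrank.p if r.logrank else np.nan,
                    "bonferroni_pass": r.bonferroni_pass,
                    "abundance_p_gene": np.nan
                    if r.abundance_p_gene is None
                    else r.abundance_p_gene,
                    "abundance_p_mir": np.nan
                    if r.abundance_p_mir is None
                    else r.abundance_p_mir,
                    "abundance_pass": bool(r.abundance_pass),
                    "n_binding_tools": -1
                    if r.binding_tools is None
                    else len(r.binding_tools),
                    "binding_tools": ""
                    if r.binding_tools is None
                    else ";".join(r.binding_tools),
                    "final_pass": r.final_pass,
                    "group1_samples": ";".join(sample_ids[list(p.group1)]) if p else "",
                }
            )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        counts = self.cascade_counts()
        return {
            "package": "mirstrat",
            "version": __version__,
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "n_samples": self.data.n_samples,
            "n_genes": len(self.data.gene_expr.feature_ids),
            "n_mirs": len(self.data.mir_expr.feature_ids),
            "bonferroni_family_size": counts["valid"],
            "bonferroni_threshold": (
                bonferroni_threshold(counts["valid"], self.config.alpha_family)
                if counts["valid"]
                else None
            ),
            "cascade": counts,
            "prediction_table_supplied": self.model.predictions is not None,
        }

    def summary(self) -> str:
        c = self.cascade_counts()
        lines = [
            "miR-gene association screen",
            "=" * 60,
            f"samples: {self.data.n_samples}   "
            f"pairs scanned: {c['scanned']} (skipped {c['skipped']})",
            f"valid pairs (sig. negative corr in Group 1 only): {c['valid']}",
            f"Bonferroni survivors (alpha={self.config.alpha_family}, "
            f"m={c['valid']}): {c['bonferroni']}",
            f"after abundance filter: {c['abundance']}",
            f"final discovery set: {c['final']}",
        ]
        final = sorted(
            self.final_pairs, key=lambda r: r.logrank.p if r.logrank else 1.0
        )
        if final:
            lines.append("-" * 60)
            lines.append(
                f"{'miR':<14}{'gene':<14}{'r1':>8}{'n1':>5}{'n2':>5}"
                f"{'logrank p':>12}{'tools':>6}"
            )
            for r in final:
                ntools = "-" if r.binding_tools is None else str(len(r.binding_tools))
                lines.append(
                    f"{r.mir_id:<14}{r.gene_id:<14}{r.partition.corr1.r:>8.3f}"
                    f"{len(r.partition.group1):>5}{len(r.partition.group2):>5}"
                    f"{r.logrank.p:>12.3e}{ntools:>6}"
                )
        return "\n".join(lines)

    # -- follow-up analyses ----------------------------------------------
    def permutation_fdr(
        self, n_iterations: int | None = None, seed: int | None = None
    ) -> FDRResult:
        return permutation_fdr(self.pairs, self.data, self.config, n_iterations, seed)

    def sensitivity(
        self,
        mir_id: str,
        gene_id: str,
        n_triples: int = 100,
        mode: str = "sampled",
        seed: int | None = None,
    ) -> SensitivityResult:
        return sensitivity_analysis(
            self.data.mir_expr.row(mir_id),
            self.data.gene_expr.row(gene_id),
            n_triples=n_triples,
            mode=mode,
            seed=self.config.seed if seed is None else seed,
            mir_id=mir_id,
            gene_id=gene_id,
            admission=self.config.admission,
            method=self.config.correlation_method,
        )

    def covariate_balance(self, mir_id: str, gene_id: str) -> pd.DataFrame:
        r = self.get_pair(mir_id, gene_id)
        if r.partition is None:
            raise ValueError("pair was skipped; no partition available")
        return covariate_balance(r.partition, self.data.clinical)

    def plot_km(self, mir_id: str, gene_id: str, ax=None):
        from .plotting import plot_km_pair

        r = self.get_pair(mir_id, gene_id)
        if r.partition is None:
            raise ValueError("pair was skipped; no partition available")
        return plot_km_pair(r, self.data.clinical, ax=ax)

    # -- persistence -----------------------------------------------------
    def write(self, directory) -> dict[str, Path]:
        """Write the per-pair TSV and the JSON run manifest."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "results": directory / "pair_results.tsv",
            "manifest": directory / "manifest.json",
        }
        self.to_frame().to_csv(paths["results"], sep="\t", index=False, float_format="%.6g")
        paths["manifest"].write_text(json.dumps(self.manifest(), indent=1) + "\n")
        return paths
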