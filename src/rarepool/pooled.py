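"""Pooled gene-level rare-variant association tests with permutation p-values.

Four tests are provided, all built on the same weighted-burden score
statistic.  For a gene with minor-allele count columns x_i and per-variant
weights w_i, each sample's burden is C_j = sum_i w_i x_ji and the statistic is
the standardized score of the slope in the linear regression of the phenotype
y on C:

    z = sum_j C_j (y_j - ybar) / ( sd(y) * sqrt(sum_j (C_j - Cbar)^2) )

with sd(y) the divide-by-n standard deviation.  z is the regression slope
divided by its null standard error; because ybar and sd(y) are invariant
under permutation of y, permuted statistics are plain dot products, which is
what makes re-optimizing the variable threshold inside every permutation
affordable.

* ``T1`` / ``T5`` (fixed threshold): w_i = 1 if maf_i < T (strictly), else 0,
  with T = 0.01 / 0.05.
* ``WS`` (weighted sum): w_i = 1 / sqrt(n p_i (1 - p_i)), the inverse square
  root of the expected genotype variance, so rarer variants weigh more.  The
  factor n cancels in z.
* ``VT`` (variable threshold): the candidate thresholds are the distinct
  observed MAFs of the gene; the statistic is z_max, the maximum z over
  candidates (variant i enters at threshold t iff maf_i <= t); the optimum is
  re-found inside every permutation, so a permuted dataset may attain its
  maximum at a different threshold than the observed data.

Significance always comes from permutation of the phenotype with the add-one
estimator p = (1 + #{z_k >= z_obs}) / (1 + P); binary phenotypes go through
the identical linear score path.  Monomorphic variants (sample maf = 0) are
dropped before weighting.  Within one gene all requested tests share a single
permutation stream whose seed is derived from (global seed, gene name), so
results do not depend on gene processing order and cross-test comparisons are
paired.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000
DEFAULT_THRESHOLDS = (0.01, 0.05)
#: largest sample size for which exhaustive enumeration of all n! phenotype
#: permutations is permitted (8! = 40,320)
EXHAUSTIVE_SAMPLE_CAP = 8
#: permutations are processed in fixed-size chunks so results are independent
#: of available memory
_PERM_CHUNK = 1024
#: relative tie guard: a permuted statistic within this of the observed one is
#: counted as >= (permutations that merely re-pair identical values are exact
#: ties mathematically but can differ in the last ulp)
_TIE_RTOL = 1e-12

SIDEDNESS = ("one-sided-greater", "two-sided")


class NoQualifyingVariants(ValueError):
    """Every weight is zero: the gene has no variant this test can use."""


class DegeneratePhenotype(ValueError):
    """The phenotype is constant; no association is defined."""


@dataclasses.dataclass(frozen=True)
class PermutationPlan:
    """How permutation p-values are obtained.

    ``monte-carlo`` draws ``n_perm`` random phenotype shuffles; ``exhaustive``
    enumerates all n! orderings (legal only for n <= EXHAUSTIVE_SAMPLE_CAP)
    and ignores ``n_perm``.
    """

    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    mode: str = "monte-carlo"

    def __post_init__(self) -> None:
        if self.mode not in ("monte-carlo", "exhaustive"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")


@dataclasses.dataclass
class TestResult:
    """One gene × one test.

    ``statistic`` is the z score (z_max for VT); ``optimal_threshold`` is the
    VT cutoff attaining it (absent otherwise); ``beta_hat`` is the slope of
    the burden regression at the reported statistic, a diagnostic only.  A
    not-testable result (``testable=False``) means the gene lies outside the
    test's universe and carries no p-value.
    """

    gene_name: str
    test_name: str
    n_variants_used: int
    statistic: float | None
    optimal_threshold: float | None
    beta_hat: float | None
    n_permutations: int
    p_value: float | None
    testable: bool = True


# ---------------------------------------------------------------------------
# weights and statistics
# ---------------------------------------------------------------------------


def threshold_weights(mafs: Sequence[float], T: float) -> np.ndarray:
    """0/1 inclusion weights: w_i = 1 iff maf_i < T (strict inequality)."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("empty maf vector")
    return (mafs < T).astype(float)


def ws_weights(mafs: Sequence[float], n_samples: int) -> np.ndarray:
    """Inverse-sqrt-variance weights w_i = 1 / sqrt(n p_i (1 - p_i)).

    p_i is the full-sample minor-allele frequency; the factor n_samples
    cancels in the z statistic (which is scale-invariant in the weights), so
    only p_i (1 - p_i) matters for inference.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("empty maf vector")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if np.any(mafs <= 0.0):
        raise ValueError("maf = 0 gives zero expected variance; drop the variant first")
    if np.any(mafs > 0.5):
        raise ValueError("maf must be folded to <= 0.5")
    return 1.0 / np.sqrt(n_samples * mafs * (1.0 - mafs))


def weighted_burden(counts_gene: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-sample burden C_j = sum_i w_i x_ji."""
    counts_gene = np.asarray(counts_gene, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if counts_gene.ndim != 2 or counts_gene.shape[1] != weights.shape[0]:
        raise ValueError(
            f"shape mismatch: counts {counts_gene.shape} vs {weights.shape[0]} weights"
        )
    if not np.any(weights > 0):
        raise NoQualifyingVariants("all weights are zero: no qualifying variants")
    return counts_gene @ weights


def z_statistic(burden: np.ndarray, y: np.ndarray) -> float:
    """Standardized score statistic of the burden regression slope.

    Returns 0 when the burden is constant (no variation to associate);
    raises :class:`DegeneratePhenotype` when the phenotype is constant.
    """
    C = np.asarray(burden, dtype=float)
    y = np.asarray(y, dtype=float)
    if C.shape != y.shape or C.ndim != 1 or C.size < 2:
        raise ValueError("burden and phenotype must be equal-length vectors, n >= 2")
    sd = y.std()  # divide-by-n; permutation-invariant
    if sd == 0.0:
        raise DegeneratePhenotype("phenotype is constant")
    Cc = C - C.mean()
    ss = float(Cc @ Cc)
    if ss == 0.0:
        return 0.0
    return float((Cc @ y) / (sd * math.sqrt(ss)))


def permutation_pvalue(
    observed: float, permuted: Sequence[float], sided: str = "one-sided-greater"
) -> float:
    """Add-one permutation p-value: (1 + #{s_k >= s_obs}) / (1 + P)."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("no permuted statistics supplied")
    if sided not in SIDEDNESS:
        raise ValueError(f"sided must be one of {SIDEDNESS}")
    s_obs = abs(observed) if sided == "two-sided" else observed
    s = np.abs(permuted) if sided == "two-sided" else permuted
    count = int(np.sum(s >= s_obs - _TIE_RTOL * max(1.0, abs(s_obs))))
    return (1 + count) / (1 + permuted.size)


def gene_seed(seed: int, gene_name: str) -> int:
    """Stable per-gene seed derived from (global seed, gene name).

    Uses a cryptographic digest rather than ``hash()`` so runs are
    reproducible across interpreter sessions.
    """
    digest = hashlib.sha256(f"{seed}:{gene_name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# the shared permutation engine
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _Spec:
    """One test's burden columns for the permutation loop."""

    test_name: str
    burdens_centered: np.ndarray  # n × K, column-centered (zeroed where ss = 0)
    denoms: np.ndarray  # K, sd(y) * sqrt(ss_k) (1 where ss = 0)
    candidates: np.ndarray | None  # VT thresholds, ascending; None otherwise
    n_variants_used: int


def _make_spec(test_name, counts, mafs, n_samples, thresholds) -> _Spec | None:
    """Build the burden column matrix for one test; None if not testable."""
    if test_name in ("T1", "T5") or test_name.startswith("fixed("):
        T = {"T1": 0.01, "T5": 0.05}.get(test_name)
        if T is None:
            T = float(test_name[6:-1])
        w = threshold_weights(mafs, T) if mafs.size else np.empty(0)
        if not np.any(w > 0):
            return None
        B = counts[:, w > 0].sum(axis=1, dtype=float)[:, None]
        return _Spec(test_name, B, np.empty(0), None, int((w > 0).sum()))
    if test_name == "WS":
        if mafs.size == 0:
            return None
        w = ws_weights(mafs, n_samples)
        B = (counts @ w)[:, None]
        return _Spec(test_name, B, np.empty(0), None, mafs.size)
    if test_name == "VT":
        if mafs.size == 0:
            return None
        cands = np.unique(mafs)  # ascending, so argmax ties pick the smallest T
        B = np.column_stack(
            [counts[:, mafs <= t].sum(axis=1, dtype=float) for t in cands]
        )
        return _Spec(test_name, B, np.empty(0), cands, mafs.size)
    raise ValueError(f"unknown test name {test_name!r}")


def _finalize_spec(spec: _Spec, sd_y: float) -> None:
    B = spec.burdens_centered
    Bc = B - B.mean(axis=0)
    ss = (Bc**2).sum(axis=0)
    degenerate = ss == 0.0
    Bc[:, degenerate] = 0.0  # z = 0 for constant-burden columns
    denoms = sd_y * np.sqrt(np.where(degenerate, 1.0, ss))
    spec.burdens_centered = Bc
    spec.denoms = denoms


def _perm_chunks(y: np.ndarray, plan: PermutationPlan, rng_seed: int):
    """Yield (P_total, iterator of permuted-phenotype chunks)."""
    n = y.size
    if plan.mode == "exhaustive":
        if n > EXHAUSTIVE_SAMPLE_CAP:
            raise ValueError(
                f"exhaustive mode allowed only for n <= {EXHAUSTIVE_SAMPLE_CAP}, got {n}"
            )
        total = math.factorial(n)

        def gen():
            it = itertools.permutations(y)
            while True:
                block = list(itertools.islice(it, _PERM_CHUNK))
                if not block:
                    return
                yield np.asarray(block, dtype=float)

        return total, gen()
    rng = np.random.default_rng(rng_seed)
    total = plan.n_perm

    def gen():
        left = total
        while left > 0:
            c = min(_PERM_CHUNK, left)
            block = np.tile(y, (c, 1))
            rng.permuted(block, axis=1, out=block)
            yield block
            left -= c

    return total, gen()


def run_gene_tests(
    gene_name: str,
    counts_gene: np.ndarray,
    mafs: Sequence[float],
    y: Sequence[float],
    tests: Sequence[str] = ("T1", "T5", "WS", "VT"),
    plan: PermutationPlan = PermutationPlan(),
    sided: str = "one-sided-greater",
) -> dict[str, TestResult]:
    """Run the requested tests on one gene with a shared permutation stream.

    ``counts_gene`` is the samples × gene-variants minor-allele count
    submatrix, ``mafs`` the matching sample MAFs.  Monomorphic variants are
    dropped here.  All tests see the same phenotype shuffles.
    """
    if sided not in SIDEDNESS:
        raise ValueError(f"sided must be one of {SIDEDNESS}")
    y = np.asarray(y, dtype=float)
    counts_gene = np.asarray(counts_gene)
    mafs = np.asarray(mafs, dtype=float)
    if counts_gene.shape[0] != y.size:
        raise ValueError("phenotype length does not match genotype rows")
    sd_y = y.std()
    if sd_y == 0.0:
        raise DegeneratePhenotype("phenotype is constant")

    poly = mafs > 0.0
    counts_p = counts_gene[:, poly].astype(float)
    mafs_p = mafs[poly]
    n = y.size

    results: dict[str, TestResult] = {}
    specs: list[_Spec] = []
    for t in tests:
        spec = _make_spec(t, counts_p, mafs_p, n, DEFAULT_THRESHOLDS)
        if spec is None:
            results[t] = TestResult(
                gene_name, t, 0, None, None, None, 0, None, testable=False
            )
        else:
            _finalize_spec(spec, sd_y)
            specs.append(spec)
    if not specs:
        return results

    two_sided = sided == "two-sided"
    obs_stat: dict[str, float] = {}
    obs_crit: dict[str, float] = {}
    obs_thr: dict[str, float | None] = {}
    obs_beta: dict[str, float | None] = {}
    counts_ge = {s.test_name: 0 for s in specs}
    for s in specs:
        zs = (y @ s.burdens_centered) / s.denoms
        crit = np.abs(zs) if two_sided else zs
        k = int(np.argmax(crit))
        obs_stat[s.test_name] = float(zs[k])
        obs_crit[s.test_name] = float(crit[k])
        obs_thr[s.test_name] = float(s.candidates[k]) if s.candidates is not None else None
        bc = s.burdens_centered[:, k]
        ssb = float(bc @ bc)
        obs_beta[s.test_name] = float((bc @ y) / ssb) if ssb > 0 else None

    total, chunks = _perm_chunks(y, plan, gene_seed(plan.seed, gene_name))
    for block in chunks:
        for s in specs:
            Z = (block @ s.burdens_centered) / s.denoms
            stat = np.abs(Z).max(axis=1) if two_sided else Z.max(axis=1)
            o = obs_crit[s.test_name]
            counts_ge[s.test_name] += int(np.sum(stat >= o - _TIE_RTOL * max(1.0, abs(o))))

    for s in specs:
        p = (1 + counts_ge[s.test_name]) / (1 + total)
        results[s.test_name] = TestResult(
            gene_name=gene_name,
            test_name=s.test_name,
            n_variants_used=s.n_variants_used,
            statistic=obs_stat[s.test_name],
            optimal_threshold=obs_thr[s.test_name],
            beta_hat=obs_beta[s.test_name],
            n_permutations=total,
            p_value=p,
        )
    return {t: results[t] for t in tests}


# ---------------------------------------------------------------------------
# per-test wrappers operating on the full dataset containers
# ---------------------------------------------------------------------------


def _gene_slice(G, V, idx: Mapping[str, np.ndarray], gene: str):
    if gene not in idx:
        raise KeyError(f"gene {gene!r} not in gene index")
    cols = np.asarray(idx[gene], dtype=np.int64)
    mafs = V["maf"].to_numpy(dtype=float)
    if np.isnan(mafs).any():
        raise ValueError("variant table maf column is unset; run compute_maf first")
    return G.counts[:, cols], mafs[cols]


def fixed_threshold_test(
    gene, G, V, idx, y, T: float, plan: PermutationPlan = PermutationPlan(),
    sided: str = "one-sided-greater",
) -> TestResult:
    """Burden test on variants with maf < T.  T=0.01 is T1, T=0.05 is T5."""
    name = "T1" if T == 0.01 else "T5" if T == 0.05 else f"fixed({T:g})"
    counts, mafs = _gene_slice(G, V, idx, gene)
    return run_gene_tests(gene, counts, mafs, y, tests=(name,), plan=plan, sided=sided)[name]


def weighted_sum_test(
    gene, G, V, idx, y, plan: PermutationPlan = PermutationPlan(),
    sided: str = "one-sided-greater",
) -> TestResult:
    """Inverse-variance weighted burden test over all polymorphic gene variants."""
    counts, mafs = _gene_slice(G, V, idx, gene)
    return run_gene_tests(gene, counts, mafs, y, tests=("WS",), plan=plan, sided=sided)["WS"]


def variable_threshold_test(
    gene, G, V, idx, y, plan: PermutationPlan = PermutationPlan(),
    sided: str = "one-sided-greater",
) -> TestResult:
    """Maximize z over all observed-MAF cutoffs; permutation re-maximizes."""
    counts, mafs = _gene_slice(G, V, idx, gene)
    return run_gene_tests(gene, counts, mafs, y, tests=("VT",), plan=plan, sided=sided)["VT"]
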