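"""Population-genetic statistics for validated SNP panels.

Covers per-locus diversity (MAF, observed and unbiased expected
heterozygosity), exact Hardy-Weinberg tests by full enumeration of the
heterozygote-count distribution conditional on allele counts (Levene),
multilocus Weir-Cockerham (1984) F-statistics with permutation
significance and sequential-Bonferroni (Holm) correction, a permutation
F_ST outlier scan with Benjamini-Hochberg q-values, and admixture
clustering by EM on the no-LD admixture likelihood with Evanno delta-K /
Pritchard model choice.

Estimator notes: theta (F_ST) is the ratio of summed variance components
a / (a+b+c) over loci; F_IS within one population is 1 - sum(c)/sum(b+c)
of the single-population variance components.  Missing genotypes are
excluded pairwise per locus, and loci monomorphic within a comparison
contribute zero variance components.  Permutation p-values use the
add-one rule p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from txsnp.io_formats import MISSING_CALL, GenotypeMatrix

DEFAULT_N_PERMUTATIONS = 1000


# ---------------------------------------------------------------------------
# per-locus diversity and exact HWE

def hwe_enumeration(n_a: int, n_b: int) -> dict[int, float]:
    """Exact distribution of the heterozygote count given allele counts.

    Returns P(n_AB = h) for every admissible h (same parity as n_a,
    0 <= h <= min(n_a, n_b)), for n = (n_a + n_b)/2 diploids.
    """
    if (n_a + n_b) % 2:
        raise ValueError("odd total allele count")
    n = (n_a + n_b) // 2
    if n_a == 0 or n_b == 0:
        return {0: 1.0}
    hs = list(range(min(n_a, n_b) % 2 if n_a % 2 else 0,
                    min(n_a, n_b) + 1, 2))
    # log P(h) = log n! - log n_AA! - log h! - log n_BB! + h log 2
    #            + log n_a! + log n_b! - log (2n)!
    logs = []
    for h in hs:
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        logs.append(
            gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(h + 1)
            - gammaln(n_bb + 1) + h * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )
    probs = np.exp(np.array(logs))
    probs /= probs.sum()   # guard rounding; analytically sums to 1
    return dict(zip(hs, probs.tolist()))


def hwe_exact_pvalue(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg test: the sum of probabilities of
    heterozygote counts no more likely than the observed one."""
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    dist = hwe_enumeration(n_a, n_b)
    p_obs = dist.get(n_het)
    if p_obs is None:
        raise ValueError(f"heterozygote count {n_het} inadmissible for "
                         f"allele counts ({n_a}, {n_b})")
    return float(min(1.0, sum(p for p in dist.values()
                              if p <= p_obs * (1 + 1e-12))))


def locus_stats(matrix: GenotypeMatrix,
                group: str | None = None) -> pd.DataFrame:
    """Per-locus MAF, H_o, unbiased H_e and exact HWE p-value.

    ``group`` restricts to one population label.  H_e uses the small-sample
    correction 2n/(2n-1) * 2p(1-p).  Monomorphic loci report
    ho = he = maf = 0 and hwe_p = 1.
    """
    if group is not None:
        idx = matrix.populations[matrix.populations == group].index
        if len(idx) == 0:
            raise ValueError(f"no individuals in group {group!r}")
        matrix = matrix.subset(individuals=idx)
    rows = []
    for locus in matrix.loci:
        calls = [c for c in matrix.calls[locus] if c != MISSING_CALL]
        n = len(calls)
        if n == 0:
            raise ValueError(f"no called individuals at locus {locus!r}")
        alleles = sorted(set("".join(calls)))
        if len(alleles) < 2:
            rows.append({"locus": locus, "n_called": n, "maf": 0.0,
                         "ho": 0.0, "he": 0.0, "hwe_p": 1.0})
            continue
        a, b = alleles
        n_het = sum(c[0] != c[1] for c in calls)
        n_aa = sum(c == a + a for c in calls)
        n_bb = sum(c == b + b for c in calls)
        p = (2 * n_aa + n_het) / (2 * n)
        rows.append({
            "locus": locus,
            "n_called": n,
            "maf": min(p, 1 - p),
            "ho": n_het / n,
            "he": (2 * n / (2 * n - 1)) * 2 * p * (1 - p),
            "hwe_p": hwe_exact_pvalue(n_aa, n_het, n_bb),
        })
    return pd.DataFrame(rows).set_index("locus")


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components

def _group_tallies(dosage: np.ndarray, masks: list[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (group, locus): sample size, ref-allele frequency, het frequency."""
    G, L = len(masks), dosage.shape[1]
    n = np.zeros((G, L))
    p = np.zeros((G, L))
    h = np.zeros((G, L))
    for g, mask in enumerate(masks):
        sub = dosage[mask]
        called = sub >= 0
        n[g] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[g] = np.where(n[g] > 0,
                            np.where(called, sub, 0).sum(axis=0) / (2 * n[g]),
                            0.0)
            h[g] = np.where(n[g] > 0, (sub == 1).sum(axis=0) / n[g], 0.0)
    return n, p, h


def _wc_components(dosage: np.ndarray, masks: list[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-locus variance components (a, b, c).

    Loci with fewer than two informative groups, mean sample size <= 1, or
    no allelic variation contribute zeros.
    """
    n, p, h = _group_tallies(dosage, masks)
    return _wc_components_from_tallies(n, p, h)


def _wc_components_from_tallies(n: np.ndarray, p: np.ndarray, h: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray,
                                           np.ndarray]:
    """Variance components from per-(group, locus) sample sizes, allele
    frequencies and heterozygote frequencies (arrays of shape (G, L))."""
    present = n > 0
    r = present.sum(axis=0).astype(float)
    L = n.shape[1]
    a = np.zeros(L)
    b = np.zeros(L)
    c = np.zeros(L)
    ok = r >= 2
    if not ok.any():
        return a, b, c
    nsum = n.sum(axis=0)
    n_bar = np.where(ok, nsum / np.maximum(r, 1), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = np.where(
            ok & (r > 1),
            (nsum - (n ** 2).sum(axis=0) / np.maximum(nsum, 1))
            / np.maximum(r - 1, 1),
            0.0,
        )
        p_bar = np.where(nsum > 0, (n * p).sum(axis=0) / np.maximum(nsum, 1),
                         0.0)
        s2 = np.where(
            ok,
            (n * (p - p_bar) ** 2).sum(axis=0)
            / np.maximum((r - 1) * n_bar, 1e-300),
            0.0,
        )
        h_bar = np.where(nsum > 0, (n * h).sum(axis=0) / np.maximum(nsum, 1),
                         0.0)
        pq = p_bar * (1 - p_bar)
        usable = ok & (n_bar > 1) & (n_c > 0) & (pq + s2 > 0)
        inner = pq - (r - 1) / np.maximum(r, 1) * s2 - h_bar / 4
        a = np.where(usable,
                     n_bar / np.maximum(n_c, 1e-300)
                     * (s2 - inner / np.maximum(n_bar - 1, 1e-300)),
                     0.0)
        b = np.where(usable,
                     n_bar / np.maximum(n_bar - 1, 1e-300)
                     * (pq - (r - 1) / np.maximum(r, 1) * s2
                        - (2 * n_bar - 1) / (4 * n_bar) * h_bar),
                     0.0)
        c = np.where(usable, h_bar / 2, 0.0)
    return a, b, c


def theta_multilocus(dosage: np.ndarray, labels: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta: ratio of summed components."""
    groups = np.unique(labels)
    masks = [labels == g for g in groups]
    a, b, c = _wc_components(dosage, masks)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def _fis_single_group(sub: np.ndarray) -> float:
    """Multilocus F_IS of one population: 1 - sum(c)/sum(b+c) with the
    single-population Weir-Cockerham components."""
    called = sub >= 0
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n),
                     0.0)
        h = np.where(n > 0, (sub == 1).sum(axis=0) / n, 0.0)
        pq = p * (1 - p)
        usable = (n > 1) & (pq + h > 0)
        b = np.where(usable,
                     n / np.maximum(n - 1, 1e-300)
                     * (pq - (2 * n - 1) / (4 * n) * h),
                     0.0)
        c = np.where(usable, h / 2, 0.0)
    denom = (b + c).sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - c.sum() / denom)


@dataclass
class FstResult:
    overall_fst: float
    overall_p: float
    pairwise: pd.DataFrame          # theta below usage; symmetric here
    pairwise_p: pd.DataFrame
    significant: pd.DataFrame       # Holm-corrected at alpha
    fis: pd.Series
    fis_p: pd.Series
    n_permutations: int
    alpha: float


def weir_cockerham(matrix: GenotypeMatrix,
                   groups: pd.Series | None = None,
                   n_permutations: int = DEFAULT_N_PERMUTATIONS,
                   alpha: float = 0.05,
                   seed: int | None = None) -> FstResult:
    """Multilocus theta overall and for every pair of groups, F_IS within
    each group, with permutation p-values and Holm correction across the
    pairwise tests.

    ``groups`` defaults to the matrix's population labels; pass any series
    aligned to the individuals (e.g. breed x GH-genotype) for finer
    partitions.
    """
    labels = (groups if groups is not None else matrix.populations)
    labels = labels.loc[matrix.calls.index].to_numpy()
    names = sorted(pd.unique(labels))
    for g in names:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    if len(names) < 2:
        raise ValueError("F_ST needs at least two groups")
    rng = np.random.default_rng(seed)
    dosage = matrix.dosage().astype(np.int8)

    overall = theta_multilocus(dosage, labels)
    overall_p = _perm_pvalue_theta(dosage, labels, overall, n_permutations,
                                   rng)

    pw = pd.DataFrame(np.nan, index=names, columns=names)
    pw_p = pd.DataFrame(np.nan, index=names, columns=names)
    pairs = list(itertools.combinations(names, 2))
    raw_p = []
    for g1, g2 in pairs:
        mask = (labels == g1) | (labels == g2)
        sub, sub_labels = dosage[mask], labels[mask]
        th = theta_multilocus(sub, sub_labels)
        p = _perm_pvalue_theta(sub, sub_labels, th, n_permutations, rng)
        pw.loc[g1, g2] = pw.loc[g2, g1] = th
        pw_p.loc[g1, g2] = pw_p.loc[g2, g1] = p
        raw_p.append(p)
    if pairs:
        reject, _, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    sig = pd.DataFrame(False, index=names, columns=names)
    for (g1, g2), rej in zip(pairs, reject if pairs else []):
        sig.loc[g1, g2] = sig.loc[g2, g1] = bool(rej)

    fis = {}
    fis_p = {}
    for g in names:
        sub = dosage[labels == g]
        f = _fis_single_group(sub)
        fis[g] = f
        fis_p[g] = _perm_pvalue_fis(sub, f, n_permutations, rng)
    return FstResult(
        overall_fst=overall,
        overall_p=overall_p,
        pairwise=pw,
        pairwise_p=pw_p,
        significant=sig,
        fis=pd.Series(fis),
        fis_p=pd.Series(fis_p),
        n_permutations=n_permutations,
        alpha=alpha,
    )


def _perm_pvalue_theta(dosage: np.ndarray, labels: np.ndarray,
                       observed: float, n_perm: int,
                       rng: np.random.Generator) -> float:
    if np.isnan(observed):
        return 1.0
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        t = theta_multilocus(dosage, perm)
        if not np.isnan(t) and t >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _perm_pvalue_fis(sub: np.ndarray, observed: float, n_perm: int,
                     rng: np.random.Generator) -> float:
    """Randomize alleles among individuals within the group, per locus;
    two-sided on |F_IS|."""
    if np.isnan(observed):
        return 1.0
    n, L = sub.shape
    hits = 0
    for _ in range(n_perm):
        shuffled = np.full_like(sub, -1)
        for l in range(L):
            col = sub[:, l]
            called = col >= 0
            alleles = np.repeat([1, 0], [int(col[called].sum()),
                                         int(2 * called.sum()
                                             - col[called].sum())])
            rng.shuffle(alleles)
            shuffled[called, l] = alleles[0::2] + alleles[1::2]
        f = _fis_single_group(shuffled)
        if not np.isnan(f) and abs(f) >= abs(observed):
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# outlier scan

@dataclass
class OutlierReport:
    per_locus: pd.DataFrame     # fst, p_value, q_value, outlier
    q_threshold: float
    n_permutations: int

    @property
    def outlier_loci(self) -> list[str]:
        return list(self.per_locus.index[self.per_locus["outlier"]])

    @property
    def neutral_loci(self) -> list[str]:
        return list(self.per_locus.index[~self.per_locus["outlier"]])


def outlier_scan(matrix: GenotypeMatrix,
                 groups: pd.Series | None = None,
                 n_permutations: int = DEFAULT_N_PERMUTATIONS,
                 q_threshold: float = 0.1,
                 seed: int | None = None,
                 null_model: str = "drift") -> OutlierReport:
    """F_ST outlier scan partitioning loci into neutral and outlier sets.

    An outlier is a locus whose differentiation exceeds what genome-wide
    drift explains.  Under the default ``null_model="drift"`` the null
    per-locus theta distribution is a parametric bootstrap: loci are
    resimulated under the Balding-Nichols model at the multilocus theta
    estimate, matching each locus's pooled allele frequency and per-group
    called sample sizes.  ``null_model="permutation"`` instead permutes
    individuals across groups (a no-differentiation null: only appropriate
    when the genome-wide theta is ~0, as any baseline drift then makes
    every locus look extreme).  Null thetas are pooled over loci and
    replicates; p-values get Benjamini-Hochberg q-values and loci with
    q < ``q_threshold`` are flagged.  (This scan is a frequentist stand-in
    for a Bayesian selection scan: it targets the same neutral/outlier
    partition, not a posterior.)
    """
    if n_permutations < 100:
        warnings.warn(f"only {n_permutations} permutations; p-value "
                      "resolution will be poor", stacklevel=2)
    if null_model not in ("drift", "permutation"):
        raise ValueError(f"unknown null_model {null_model!r}")
    labels = (groups if groups is not None else matrix.populations)
    labels = labels.loc[matrix.calls.index].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("outlier scan needs at least two groups")
    rng = np.random.default_rng(seed)
    dosage = matrix.dosage().astype(np.int8)
    names = np.unique(labels)
    masks = [labels == g for g in names]
    n_gl, p_gl, h_gl = _group_tallies(dosage, masks)
    a, b, c = _wc_components_from_tallies(n_gl, p_gl, h_gl)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / np.maximum(a + b + c, 1e-300),
                         np.nan)

    if null_model == "drift":
        denom = (a + b + c).sum()
        fhat = float(a.sum() / denom) if denom else 0.0
        pooled = _drift_null(rng, n_gl, p_gl, max(fhat, 0.0), n_permutations)
    else:
        null: list[np.ndarray] = []
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            pm = [perm == g for g in names]
            pa, pb, pc = _wc_components(dosage, pm)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(pa + pb + pc != 0,
                             pa / np.maximum(pa + pb + pc, 1e-300), np.nan)
            null.append(t[~np.isnan(t)])
        pooled = np.concatenate(null) if null else np.array([])
    pooled.sort()
    N = len(pooled)
    pvals = np.ones(len(theta))
    for j, t in enumerate(theta):
        if np.isnan(t):
            continue
        # count of null >= t via sorted search
        ge = N - np.searchsorted(pooled, t, side="left")
        pvals[j] = (1 + ge) / (1 + N)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    df = pd.DataFrame({
        "fst": theta,
        "p_value": pvals,
        "q_value": qvals,
        "outlier": qvals < q_threshold,
    }, index=matrix.loci)
    return OutlierReport(per_locus=df, q_threshold=q_threshold,
                         n_permutations=n_permutations)


def _drift_null(rng: np.random.Generator, n_gl: np.ndarray,
                p_gl: np.ndarray, fhat: float, n_reps: int) -> np.ndarray:
    """Pooled null per-locus thetas: resimulate every locus under
    Balding-Nichols drift at the genome-wide theta, keeping each locus's
    pooled allele frequency and per-group called sample sizes."""
    G, L = n_gl.shape
    nsum = n_gl.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_anc = np.where(nsum > 0, (n_gl * p_gl).sum(axis=0)
                         / np.maximum(nsum, 1), 0.0)
    p_anc = np.clip(p_anc, 1e-6, 1 - 1e-6)
    out = []
    for _ in range(n_reps):
        if fhat > 1e-9:
            alpha = p_anc * (1 - fhat) / fhat
            beta = (1 - p_anc) * (1 - fhat) / fhat
            p_pop = rng.beta(alpha[None, :], beta[None, :], size=(G, L))
        else:
            p_pop = np.broadcast_to(p_anc, (G, L)).copy()
        n_int = n_gl.astype(int)
        # Hardy-Weinberg genotype counts per (group, locus)
        hom_ref = rng.binomial(n_int, p_pop ** 2)
        het = rng.binomial(n_int - hom_ref,
                           np.clip(2 * p_pop * (1 - p_pop)
                                   / np.maximum(1 - p_pop ** 2, 1e-12),
                                   0, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            p_sim = np.where(n_int > 0,
                             (2 * hom_ref + het) / np.maximum(2 * n_int, 1),
                             0.0)
            h_sim = np.where(n_int > 0, het / np.maximum(n_int, 1), 0.0)
        a, b, c = _wc_components_from_tallies(n_gl.astype(float), p_sim,
                                              h_sim)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(a + b + c != 0, a / np.maximum(a + b + c, 1e-300),
                         np.nan)
        out.append(t[~np.isnan(t)])
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------------------
# admixture EM

@dataclass
class AdmixtureFit:
    """EM fit of the no-LD admixture model: each of an individual's two
    allele copies at a locus is drawn from cluster k with probability
    Q[i, k], and is the reference allele with probability P[k, l]."""

    K: int
    Q: np.ndarray               # individuals x K, rows sum to 1
    P: np.ndarray               # K x loci, entries in [0, 1]
    loglik: float
    seed: int | None
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)  # type: ignore
    individuals: list[str] = field(default_factory=list)

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{k + 1}" for k in range(self.K)]
        idx = self.individuals or range(self.Q.shape[0])
        return pd.DataFrame(self.Q, index=idx, columns=cols)


def admixture_em(matrix: GenotypeMatrix, K: int,
                 seed: int | None = None,
                 max_iter: int = 500,
                 tol: float = 1e-6) -> AdmixtureFit:
    """Fit the admixture model by EM; the log-likelihood is non-decreasing
    and iteration stops when its gain drops below ``tol``.

    K = 1 is closed-form: pooled allele frequencies and Q identically 1.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    dosage = matrix.dosage().astype(float)
    miss = dosage < 0
    d = np.where(miss, 0.0, dosage)          # ref-copy counts
    two = np.where(miss, 0.0, 2.0)           # total copies per call
    n, L = d.shape
    eps = 1e-9

    if K == 1:
        tot = two.sum(axis=0)
        p = np.where(tot > 0, d.sum(axis=0) / np.maximum(tot, 1), 0.5)
        P = np.clip(p[None, :], eps, 1 - eps)
        Q = np.ones((n, 1))
        ll = _admixture_loglik(d, two, Q, P)
        return AdmixtureFit(K=1, Q=Q, P=P, loglik=ll, seed=seed, n_iter=0,
                            converged=True, loglik_trace=np.array([ll]),
                            individuals=matrix.individuals)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    pooled = d.sum(axis=0) / np.maximum(two.sum(axis=0), 1)
    P = np.clip(pooled[None, :] + rng.normal(0, 0.05, size=(K, L)),
                0.05, 0.95)

    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities per (individual, cluster, locus) for ref
        # and alt copies.
        ref_w = Q[:, :, None] * P[None, :, :]          # n x K x L
        alt_w = Q[:, :, None] * (1 - P)[None, :, :]
        ref_r = ref_w / np.maximum(ref_w.sum(axis=1, keepdims=True), eps)
        alt_r = alt_w / np.maximum(alt_w.sum(axis=1, keepdims=True), eps)
        ref_count = d[:, None, :] * ref_r              # expected ref copies
        alt_count = (two - d)[:, None, :] * alt_r
        # M-step
        per_ind = (ref_count + alt_count).sum(axis=2)  # n x K
        Q = per_ind / np.maximum(per_ind.sum(axis=1, keepdims=True), eps)
        num = ref_count.sum(axis=0)                    # K x L
        den = num + alt_count.sum(axis=0)
        P = np.clip(np.where(den > 0, num / np.maximum(den, eps), 0.5),
                    eps, 1 - eps)
        ll = _admixture_loglik(d, two, Q, P)
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            prev = ll
            break
        prev = ll
    return AdmixtureFit(K=K, Q=Q, P=P, loglik=prev, seed=seed, n_iter=it,
                        converged=converged,
                        loglik_trace=np.array(trace),
                        individuals=matrix.individuals)


def _admixture_loglik(d: np.ndarray, two: np.ndarray,
                      Q: np.ndarray, P: np.ndarray) -> float:
    eps = 1e-300
    A = Q @ P                 # n x L: per-copy probability of ref allele
    return float((d * np.log(np.maximum(A, eps))
                  + (two - d) * np.log(np.maximum(1 - A, eps))).sum())


# ---------------------------------------------------------------------------
# model choice over K

def choose_k(fits_by_k: dict[int, list[AdmixtureFit]]) -> dict:
    """Choose the number of clusters from replicate fits per K.

    Evanno delta-K: mean over paired runs of |L(K+1) - 2L(K) + L(K-1)|
    divided by the across-run sd of L(K); k_evanno maximizes it.  The
    plateau (Pritchard-style) rule: the smallest K whose mean
    log-likelihood is within one sd of the best mean.
    """
    ks = sorted(fits_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    n_runs = {k: len(fits_by_k[k]) for k in ks}
    if min(n_runs.values()) < 2:
        raise ValueError("need >= 2 runs per K")
    runs = min(n_runs.values())
    L = np.array([[fits_by_k[k][r].loglik for r in range(runs)] for k in ks])
    mean_l = L.mean(axis=1)
    sd_l = L.std(axis=1, ddof=1)

    delta_k = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd_l[i] == 0:
            raise ValueError(f"zero across-run sd of the log-likelihood at "
                             f"K={ks[i]}")
        second = np.abs(L[i + 1] - 2 * L[i] + L[i - 1])
        delta_k[i] = second.mean() / sd_l[i]
    interior = ~np.isnan(delta_k)
    if np.nanmax(delta_k) < 1e-9:
        warnings.warn("delta-K is flat (log-likelihood linear in K); "
                      "the Evanno choice is arbitrary", stacklevel=2)
    k_evanno = ks[int(np.nanargmax(np.where(interior, delta_k, -np.inf)))]

    best = mean_l.max()
    sd_at_best = sd_l[int(np.argmax(mean_l))]
    plateau = [k for k, m in zip(ks, mean_l) if m >= best - sd_at_best]
    k_pritchard = min(plateau)

    table = pd.DataFrame({
        "K": ks,
        "mean_loglik": mean_l,
        "sd_loglik": sd_l,
        "delta_k": delta_k,
    }).set_index("K")
    return {"k_evanno": k_evanno, "k_pritchard": k_pritchard,
            "delta_k_table": table}
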