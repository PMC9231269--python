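"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are generated directly (no individual-level genotypes):
for K standardised (unit-variance) exposures instrumented by L SNPs, true
SNP-exposure effects Gamma (L x K) and direct pleiotropic SNP-outcome
effects alpha (length L) imply true SNP-outcome effects

    gamma_Yj = sum_k theta_k Gamma_jk + alpha_j ,

with theta the causal effects of the exposures on the outcome.  Observed
effects are drawn as beta_hat ~ Normal(truth, se^2) with the standard
GWAS standard error for a unit-variance trait,

    se_jk = sqrt(1 / (n * 2 maf_j (1 - maf_j))) ,

so instrument strength is controlled exactly through the noncentrality
n * 2 maf (1-maf) * gamma^2 (per-SNP expected F = noncentrality + 1).
Within one SNP, sampling errors across exposures are correlated via the
phenotypic correlation matrix rho, and exposure-outcome error correlation is
overlap_fraction * rho_xy — a first-order model of shared samples between
the exposure and outcome GWAS.  SNPs inside an LD block receive correlated
effects (marginal effects = R @ joint effects and error correlation R).

Default sample sizes mirror a large biobank exposure GWAS (n_x = 115078)
and a birthweight-scale outcome meta-analysis (n_y = 210267) with ~30%
sample overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gwas_io import GwasSummaryTable, SnpAssociation, TraitInfo, ValidationError
from .harmonise import HarmonisedRecord, HarmonisedSet, LdMatrix
from .mvmr import MvmrDataset

__all__ = [
    "SimulationScenario",
    "SyntheticTruth",
    "simulate_summary_stats",
    "make_reference_panel",
    "gamma_for_f",
]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


def gamma_for_f(f_target: float, n: float, maf: float | np.ndarray) -> float | np.ndarray:
    """True effect size giving per-SNP expected F ~ ``f_target`` at size n."""
    return np.sqrt(max(f_target - 1.0, 0.0) / (n * 2.0 * maf * (1.0 - maf)))


@dataclass
class SimulationScenario:
    """Generating parameters for one synthetic two-sample dataset."""

    k_exposures: int
    l_snps: int
    theta: np.ndarray  # length-K true causal effects
    gamma: np.ndarray | None = None  # L x K true SNP-exposure effects; drawn if None
    instruments_per_exposure: int = 20
    mean_f_target: float = 60.0  # expected per-SNP F of drawn instruments
    instrument_signs: str = "random"  # or "positive": all effects > 0
    shared_fraction: float = 0.0  # chance an instrument also hits another exposure
    alpha_mean: float = 0.0  # directional pleiotropy mean
    alpha_sd: float = 0.0  # pleiotropy spread
    rho: np.ndarray | None = None  # K x K phenotypic exposure correlations
    rho_xy: np.ndarray | None = None  # length-K exposure-outcome phenotypic corr
    n_x: float = 115078.0
    n_y: float = 210267.0
    overlap_fraction: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf: np.ndarray | None = None  # explicit per-SNP MAFs (overrides maf_range)
    ld_blocks: Sequence[tuple[int, float]] | None = None  # (size, r) from SNP 0
    palindromic_fraction: float = 0.1
    outcome_allele_swap_fraction: float = 0.3
    outcome_strand_flip_fraction: float = 0.2
    trait_ids: Sequence[str] | None = None
    outcome_id: str = "Y"
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.theta.size != self.k_exposures:
            raise ValidationError("theta length != k_exposures")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction outside [0, 1]")
        if self.trait_ids is not None and len(self.trait_ids) != self.k_exposures:
            raise ValidationError("trait_ids length != k_exposures")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float).ravel()
            if self.maf.size != self.l_snps:
                raise ValidationError("maf vector length != l_snps")
            if np.any((self.maf <= 0) | (self.maf >= 1)):
                raise ValidationError("maf values must lie strictly in (0, 1)")


@dataclass
class SyntheticTruth:
    """Generating truth paired with the emitted summary tables."""

    scenario: SimulationScenario
    snp_ids: list[str]
    maf: np.ndarray
    gamma: np.ndarray  # realised marginal L x K SNP-exposure effects
    alpha: np.ndarray  # realised direct SNP-outcome effects (pre-LD)
    gamma_y: np.ndarray  # realised marginal true SNP-outcome effects
    Bx_hat: np.ndarray
    Sx: np.ndarray
    by_hat: np.ndarray
    sy: np.ndarray
    instrument_indices: list[np.ndarray]  # true instruments per exposure
    exposures: dict[str, GwasSummaryTable] = field(default_factory=dict)
    outcome: GwasSummaryTable | None = None
    ld: LdMatrix | None = None
    rho: np.ndarray | None = None
    traits: list[TraitInfo] | None = None

    def to_mvmr_dataset(self, exposures: Sequence[int] | None = None) -> MvmrDataset:
        """Dataset over the pooled true instruments of the chosen exposures."""
        idx = list(range(self.scenario.k_exposures)) if exposures is None else list(exposures)
        snps = sorted(set(np.concatenate([self.instrument_indices[k] for k in idx])))
        ids = self.scenario.trait_ids or [f"X{k + 1}" for k in range(self.scenario.k_exposures)]
        return MvmrDataset(
            exposure_ids=[ids[k] for k in idx],
            snp_ids=[self.snp_ids[j] for j in snps],
            Bx=self.Bx_hat[np.ix_(snps, idx)],
            Sx=self.Sx[np.ix_(snps, idx)],
            by=self.by_hat[snps],
            sy=self.sy[snps],
            rho=None if self.rho is None else self.rho[np.ix_(idx, idx)],
        )

    def harmonised_set(self, k: int = 0, which: str = "true") -> HarmonisedSet:
        """Instrument set for exposure ``k`` straight from the truth arrays.

        ``which="true"`` uses the generating instrument indices;
        ``which="significant"`` uses SNPs at p < 5e-8 in the emitted effects.
        """
        if which == "true":
            idx = self.instrument_indices[k]
        elif which == "significant":
            z = np.abs(self.Bx_hat[:, k] / self.Sx[:, k])
            idx = np.flatnonzero(z > 5.451702)  # |z| for p = 5e-8
        else:
            raise ValueError(f"unknown selection '{which}'")
        ids = self.scenario.trait_ids or [f"X{i + 1}" for i in range(self.scenario.k_exposures)]
        records = [
            HarmonisedRecord(
                snp_id=self.snp_ids[j],
                beta_x=float(self.Bx_hat[j, k]),
                se_x=float(self.Sx[j, k]),
                beta_y=float(self.by_hat[j]),
                se_y=float(self.sy[j]),
                eaf=float(self.maf[j]),
            )
            for j in idx
        ]
        return HarmonisedSet(exposure_id=ids[k], outcome_id=self.scenario.outcome_id, records=records)


def _block_structure(l_snps: int, ld_blocks) -> list[tuple[np.ndarray, float]]:
    """[(index array, r)] covering all SNPs; unlisted SNPs are singletons."""
    blocks: list[tuple[np.ndarray, float]] = []
    pos = 0
    if ld_blocks:
        for size, r in ld_blocks:
            if pos + size > l_snps:
                raise ValidationError("LD blocks exceed number of SNPs")
            blocks.append((np.arange(pos, pos + size), float(r)))
            pos += size
    if pos < l_snps:
        blocks.append((np.arange(pos, l_snps), 0.0))
    return blocks


def _draw_gamma(scn: SimulationScenario, maf: np.ndarray, rng) -> tuple[np.ndarray, list[np.ndarray]]:
    L, K, ipe = scn.l_snps, scn.k_exposures, scn.instruments_per_exposure
    if scn.gamma is not None:
        gamma = np.asarray(scn.gamma, dtype=float)
        if gamma.shape != (L, K):
            raise ValidationError(f"gamma shape {gamma.shape} != ({L}, {K})")
        instruments = [np.flatnonzero(gamma[:, k] != 0) for k in range(K)]
        return gamma.copy(), instruments
    if K * ipe > L:
        raise ValidationError("not enough SNPs for instruments_per_exposure per exposure")
    gamma = np.zeros((L, K))
    instruments = []
    for k in range(K):
        idx = np.arange(k * ipe, (k + 1) * ipe)
        base = gamma_for_f(scn.mean_f_target, scn.n_x, maf[idx])
        signs = (
            rng.choice([-1.0, 1.0], size=ipe)
            if scn.instrument_signs == "random"
            else np.ones(ipe)
        )
        gamma[idx, k] = base * rng.uniform(0.7, 1.3, size=ipe) * signs
        if scn.shared_fraction > 0 and K > 1:
            shared = idx[rng.random(ipe) < scn.shared_fraction]
            for j in shared:
                other = int(rng.choice([i for i in range(K) if i != k]))
                gamma[j, other] = 0.5 * gamma[j, k] * rng.choice([-1.0, 1.0])
        instruments.append(idx)
    return gamma, instruments


def _error_cholesky(scn: SimulationScenario) -> np.ndarray:
    """Cholesky of the (K+1) cross-trait sampling-error correlation."""
    K = scn.k_exposures
    rho = np.eye(K) if scn.rho is None else np.asarray(scn.rho, dtype=float)
    rho_xy = np.zeros(K) if scn.rho_xy is None else np.asarray(scn.rho_xy, dtype=float).ravel()
    C = np.empty((K + 1, K + 1))
    C[:K, :K] = rho
    C[:K, K] = C[K, :K] = scn.overlap_fraction * rho_xy
    C[K, K] = 1.0
    try:
        return np.linalg.cholesky(C + 1e-12 * np.eye(K + 1))
    except np.linalg.LinAlgError:
        raise ValidationError("rho / overlap correlation matrix is not positive semi-definite")


def _alleles_and_eaf(scn: SimulationScenario, maf: np.ndarray, rng):
    L = scn.l_snps
    palindromic = rng.random(L) < scn.palindromic_fraction
    alleles = []
    for j in range(L):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[int(rng.integers(len(pool)))])
    eaf = np.where(rng.random(L) < 0.5, maf, 1.0 - maf)
    return alleles, eaf


def simulate_summary_stats(
    scenario: SimulationScenario, emit_tables: bool = True
) -> SyntheticTruth:
    """Draw one synthetic two-sample summary dataset from ``scenario``.

    All randomness comes from ``scenario.seed``.  With ``emit_tables=False``
    only the effect arrays are populated (fast path for repeated simulation).
    """
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    L, K = scn.l_snps, scn.k_exposures
    maf = scn.maf if scn.maf is not None else rng.uniform(*scn.maf_range, size=L)
    gamma_joint, instruments = _draw_gamma(scn, maf, rng)
    alpha = (
        rng.normal(scn.alpha_mean, scn.alpha_sd, size=L)
        if (scn.alpha_mean != 0 or scn.alpha_sd != 0)
        else np.zeros(L)
    )
    gy_joint = gamma_joint @ scn.theta + alpha

    blocks = _block_structure(L, scn.ld_blocks)
    gamma = gamma_joint.copy()
    gamma_y = gy_joint.copy()
    # marginal (LD-tagged) effects and block-correlated sampling errors
    chol_c = _error_cholesky(scn)
    Z = rng.standard_normal((L, K + 1)) @ chol_c.T
    r_rows = []
    for idx, r in blocks:
        if r != 0.0 and idx.size > 1:
            R = np.full((idx.size, idx.size), r)
            np.fill_diagonal(R, 1.0)
            gamma[idx] = R @ gamma_joint[idx]
            gamma_y[idx] = R @ gy_joint[idx]
            Z[idx] = np.linalg.cholesky(R + 1e-12 * np.eye(idx.size)) @ Z[idx]
        r_rows.append((idx, r))

    Sx = np.sqrt(1.0 / (scn.n_x * 2.0 * maf * (1.0 - maf)))[:, None] * np.ones((1, K))
    sy = np.sqrt(1.0 / (scn.n_y * 2.0 * maf * (1.0 - maf)))
    Bx_hat = gamma + Z[:, :K] * Sx
    by_hat = gamma_y + Z[:, K] * sy

    snp_ids = [f"rs{j + 1:05d}" for j in range(L)]
    truth = SyntheticTruth(
        scenario=scn,
        snp_ids=snp_ids,
        maf=maf,
        gamma=gamma,
        alpha=alpha,
        gamma_y=gamma_y,
        Bx_hat=Bx_hat,
        Sx=Sx,
        by_hat=by_hat,
        sy=sy,
        instrument_indices=instruments,
        rho=np.eye(K) if scn.rho is None else np.asarray(scn.rho, dtype=float),
    )
    if not emit_tables:
        return truth

    from scipy import stats as _st

    alleles, eaf = _alleles_and_eaf(scn, maf, rng)
    ids = list(scn.trait_ids) if scn.trait_ids is not None else [f"X{k + 1}" for k in range(K)]
    for k, tid in enumerate(ids):
        p = np.maximum(2.0 * _st.norm.sf(np.abs(Bx_hat[:, k] / Sx[:, k])), 5e-324)
        truth.exposures[tid] = GwasSummaryTable(
            trait_id=tid,
            records=[
                SnpAssociation(
                    snp_id=snp_ids[j],
                    effect_allele=alleles[j][0],
                    other_allele=alleles[j][1],
                    eaf=float(eaf[j]),
                    beta=float(Bx_hat[j, k]),
                    se=float(Sx[j, k]),
                    pvalue=float(p[j]),
                    n=scn.n_x,
                )
                for j in range(L)
            ],
        )

    # outcome table, with a fraction of SNPs reported with swapped allele
    # labels or on the opposite strand — harmonisation must undo both
    swap = rng.random(L) < scn.outcome_allele_swap_fraction
    flip = rng.random(L) < scn.outcome_strand_flip_fraction
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    p_y = np.maximum(2.0 * _st.norm.sf(np.abs(by_hat / sy)), 5e-324)
    out_records = []
    for j in range(L):
        ea, oa = alleles[j]
        beta, f = float(by_hat[j]), float(eaf[j])
        if swap[j]:
            ea, oa = oa, ea
            beta, f = -beta, 1.0 - f
        if flip[j] and comp[ea] != oa:  # strand flip is a no-op label-wise for palindromes
            ea, oa = comp[ea], comp[oa]
        out_records.append(
            SnpAssociation(
                snp_id=snp_ids[j],
                effect_allele=ea,
                other_allele=oa,
                eaf=f,
                beta=beta,
                se=float(sy[j]),
                pvalue=float(p_y[j]),
                n=scn.n_y,
            )
        )
    truth.outcome = GwasSummaryTable(trait_id=scn.outcome_id, records=out_records)

    r_full = np.eye(L)
    for idx, r in r_rows:
        if r != 0.0 and idx.size > 1:
            r_full[np.ix_(idx, idx)] = r
            r_full[idx, idx] = 1.0
    truth.ld = LdMatrix(snp_ids=snp_ids, r=r_full)
    return truth


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

#: (trait_id, class, lipoprotein role, true causal effect on the outcome)
_PANEL = [
    ("glucose", "glycolysis", "none", 0.33),
    ("glutamine", "amino acids", "none", 0.09),
    ("alanine", "amino acids", "none", 0.14),
    ("isoleucine", "amino acids", "none", 0.0),
    ("pyruvate", "glycolysis", "none", 0.0),
    ("bohbutyrate", "ketone bodies", "none", 0.0),
    ("total_lipids_large_ldl", "lipoprotein subclasses", "total-lipids-in-subclass", 0.0),
    ("total_lipids_small_ldl", "lipoprotein subclasses", "total-lipids-in-subclass", 0.0),
    ("total_lipids_large_hdl", "lipoprotein subclasses", "total-lipids-in-subclass", 0.0),
    ("apob", "apolipoproteins", "none", 0.0),
    ("creatinine", "fluid balance", "none", 0.0),
    ("glycoprotein_acetyls", "inflammation", "none", 0.0),
]
_PANEL_DUP = ("total_lipids_small_ldl", "total_lipids_large_ldl")  # near-duplicate pair
_PANEL_NO_INSTRUMENTS = "glycoprotein_acetyls"  # exercises the K = 0 path
_PANEL_IPE = 20  # instruments per instrumented trait
_PANEL_MEAN_F = 100.0  # within the mean-F range a large biobank GWAS yields


def make_reference_panel(seed: int = 0) -> SyntheticTruth:
    """A 12-trait panel emulating a reduced NMR metabolomics study.

    Three causal traits (glucose-like 0.33, glutamine-like 0.09, alanine-like
    0.14, in SD-outcome per SD-exposure units) and nine null traits,
    including one near-duplicate pair (rg^2 > 0.985, to exercise
    genetic-correlation pruning) and one trait with no genome-wide
    significant SNPs (to exercise the missing-instruments path); palindromic
    SNPs at varied MAFs exercise the ambiguity rule.  Trait metadata is
    attached on ``.traits``.
    """
    ids = [t for t, _, _, _ in _PANEL]
    theta = np.array([th for _, _, _, th in _PANEL])
    k = len(ids)
    dup, dup_src = _PANEL_DUP[0], _PANEL_DUP[1]
    instrumented = [t for t in ids if t not in {dup, _PANEL_NO_INSTRUMENTS}]
    l_extra = 20  # junk SNPs with no effect anywhere
    l_snps = len(instrumented) * _PANEL_IPE + l_extra

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A7E1]))
    maf = rng.uniform(0.05, 0.5, size=l_snps)
    gamma = np.zeros((l_snps, k))
    col = {t: i for i, t in enumerate(ids)}
    for b, trait in enumerate(instrumented):
        idx = np.arange(b * _PANEL_IPE, (b + 1) * _PANEL_IPE)
        base = gamma_for_f(_PANEL_MEAN_F, 115078.0, maf[idx])
        gamma[idx, col[trait]] = base * rng.uniform(0.7, 1.3, size=_PANEL_IPE) * rng.choice(
            [-1.0, 1.0], size=_PANEL_IPE
        )
    # near-duplicate: same SNP effects as its partner plus 1% relative noise
    gamma[:, col[dup]] = gamma[:, col[dup_src]] * (
        1.0 + 0.01 * rng.standard_normal(l_snps)
    )

    # phenotypic correlations: weak global 0.05, +0.15 within trait class,
    # near-unity for the duplicate pair; PSD by construction (sum of PSD
    # rank-one blocks plus a positive diagonal)
    rho = np.full((k, k), 0.05)
    classes = [c for _, c, _, _ in _PANEL]
    for i in range(k):
        for j in range(k):
            if i != j and classes[i] == classes[j]:
                rho[i, j] += 0.15
    i, j = col[dup], col[dup_src]
    rho[i, j] = rho[j, i] = 0.95
    np.fill_diagonal(rho, 1.0)

    scenario = SimulationScenario(
        k_exposures=k,
        l_snps=l_snps,
        theta=theta,
        gamma=gamma,
        maf=maf,  # gamma above was calibrated against exactly these MAFs
        rho=rho,
        rho_xy=np.clip(theta, -0.5, 0.5),
        n_x=115078.0,
        n_y=210267.0,
        overlap_fraction=0.3,
        palindromic_fraction=0.15,
        trait_ids=ids,
        outcome_id="birthweight",
        seed=int(np.random.SeedSequence([int(seed), 0x51B]).generate_state(1)[0] % (2**31)),
    )
    truth = simulate_summary_stats(scenario)
    truth.traits = [
        TraitInfo(
            trait_id=t,
            display_name=t.replace("_", " "),
            trait_class=c,
            is_ratio=False,
            is_composite=False,
            lipoprotein_role=role,
        )
        for t, c, role, _ in _PANEL
    ]
    return truth
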