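"""Synthetic beta matrices with known ground truth.

The generator emulates the features of promoter-array methylation data the
pipeline exploits, without any external download:

* **bimodal beta values** — most CpG sites are either largely unmethylated
  or largely methylated, with modes near 0.1 and 0.8;
* **coherent probe modules** — blocks of probes driven by a shared latent
  activation;
* **distance-decaying local correlation** — an Ornstein-Uhlenbeck field
  along a synthetic chromosome adds correlation exp(-d/lambda) between
  nearby probes;
* **missing entries** — injected completely at random;
* **planted switch markers** — probes whose on/off status flips the sign
  of a chosen fraction of inter-module correlations (the conditional
  concordant relationships the pipeline is built to detect).

Construction: a latent Gaussian copula.  Per sample, module activations
are multivariate normal with a regime-dependent correlation matrix; probe
latents mix module activation, local field and private noise with unit
marginal variance, and are pushed through the quantile map of a two-mode
Beta mixture into [0, 1].  This gives exact control of the correlation
regimes while keeping marginals bimodal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ValidationError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "worked_example_small",
    "ground_truth_module_labels",
    "marker_recovery_spec",
    "two_regime_spec",
    "distance_decay_spec",
]

#: nominal beta cutoff separating "off" from "on"; marker probes are drawn
#: state-faithfully relative to this value
MARKER_STATE_CUTOFF = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the stated synthetic world.

    Defaults give a 500-probe x 200-sample instance: 10 modules of 30
    probes, 199 unstructured probes, and one planted switch marker that
    flips half the module-pair correlations between its on and off states.
    """

    n_samples: int = 200
    n_modules: int = 10
    probes_per_module: int = 30
    n_noise_probes: int = 199
    n_markers: int = 1
    #: fraction of module *pairs* whose correlation flips sign between
    #: marker states (realised by negating a subset of modules, which
    #: keeps both regime matrices positive semi-definite)
    switch_effect: float = 0.5
    methylated_fraction: float = 0.4
    #: magnitude of the inter-module correlation in the "on" regime; the
    #: on state both strengthens co-methylation (CIMP-like concurrent
    #: methylation) and flips the sign of the switched pairs.  With
    #: switch_effect = 0 the two regimes are identical.
    on_correlation: float = 0.85
    #: the promoter propensity landscape is trimodal, as on real promoter
    #: arrays: constitutively unmethylated probes (CpG-island-like,
    #: upper-mode mass ~ Beta(1, 19)), constitutively methylated probes
    #: (Beta(19, 1)), and a ``variable_fraction`` minority of variable
    #: probes whose upper-mode mass is Beta(alpha, alpha) around 1/2.
    #: Constitutive probes fail the 15% dichotomy guard and go unscored,
    #: exactly as most array probes do in practice.
    variable_fraction: float = 0.3
    #: concentration of the variable class's upper-mode mass
    mode_weight_alpha: float = 15.0
    #: variance share of unstructured probes on the shared methylator
    #: factor in the "on" regime (0 in the off regime): the on state
    #: coordinates methylation genome-wide, CIMP-style, not only inside
    #: the planted modules.  Inactive when switch_effect yields no
    #: regime change.
    noise_on_coupling: float = 0.4
    beta_modes: tuple[float, float] = (0.1, 0.8)
    #: concentration of the two Beta mixture components; larger = tighter
    mode_concentration: float = 22.0
    null_rate: float = 0.01
    #: probe spacing along the synthetic chromosome, base pairs
    chromosome_layout: int = 100
    #: length scale of the local correlation decay exp(-d/decay_lambda)
    decay_lambda: float = 500.0
    seed: int = 0
    # -- mixing weights (unit marginal variance) --------------------------
    #: latent variance share of the module activation for module probes
    module_weight: float = 0.7
    #: local-field variance share for module probes
    local_weight: float = 0.1
    #: local-field variance share for unstructured ("noise") probes
    noise_local_weight: float = 0.15
    #: baseline ("off" regime) latent correlation between module activations
    base_correlation: float = 0.1
    #: latent mean added to regime-flipped modules when their marker is on
    #: (0 = pure correlation switch; > 0 emulates a CIMP-like
    #: hypermethylation regime that also shifts methylation levels)
    state_mean_shift: float = 0.0
    #: probability that a marker probe's drawn value contradicts its state
    marker_mislabel_rate: float = 0.0

    def validate(self) -> None:
        props = {
            "switch_effect": self.switch_effect,
            "methylated_fraction": self.methylated_fraction,
            "null_rate": self.null_rate,
            "marker_mislabel_rate": self.marker_mislabel_rate,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_samples": self.n_samples,
            "n_modules": self.n_modules,
            "probes_per_module": self.probes_per_module,
            "n_noise_probes": self.n_noise_probes,
            "n_markers": self.n_markers,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.n_modules > 0 and self.probes_per_module == 0:
            raise ValidationError("probes_per_module = 0 with n_modules > 0")
        if self.n_probes == 0:
            raise ValidationError("spec generates no probes at all")
        if self.n_samples < 1:
            raise ValidationError("need at least one sample")
        lo, hi = self.beta_modes
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0 and lo != hi):
            raise ValidationError("beta_modes must be distinct values in (0, 1)")
        if self.module_weight + self.local_weight > 1.0:
            raise ValidationError("module_weight + local_weight must be <= 1")
        if not 0.0 <= self.noise_local_weight <= 1.0:
            raise ValidationError("noise_local_weight must be in [0, 1]")
        if not 0.0 <= self.base_correlation < 1.0:
            raise ValidationError("base_correlation must be in [0, 1)")
        if not 0.0 <= self.on_correlation < 1.0:
            raise ValidationError("on_correlation must be in [0, 1)")
        if not 0.0 <= self.noise_on_coupling <= 1.0 - self.noise_local_weight:
            raise ValidationError(
                "noise_on_coupling must be in [0, 1 - noise_local_weight]"
            )
        if self.mode_weight_alpha <= 0:
            raise ValidationError("mode_weight_alpha must be > 0")
        if not 0.0 <= self.variable_fraction <= 1.0:
            raise ValidationError("variable_fraction must be in [0, 1]")

    @property
    def n_module_probes(self) -> int:
        return self.n_modules * self.probes_per_module

    @property
    def n_probes(self) -> int:
        return self.n_module_probes + self.n_noise_probes + self.n_markers


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``module_membership`` maps each probe to its planted module index, or
    -1 for unstructured probes and markers (markers are never members of a
    planted module).  ``marker_states`` is markers x samples (True = on).
    ``regime_off``/``regime_on`` are the *beta-scale* inter-module
    meta-profile correlation targets the generator expects to realise in
    each regime (computed analytically from the latent regimes and the
    quantile maps; exact for state_mean_shift = 0);
    ``latent_regime_off``/``latent_regime_on`` are the underlying latent
    correlation matrices.  ``flipped_modules`` lists the modules negated
    in the on state, and ``marker_of_module`` says which marker controls
    each of them.
    """

    marker_probe_ids: list
    module_membership: pd.Series
    marker_states: pd.DataFrame
    regime_off: pd.DataFrame
    regime_on: pd.DataFrame
    latent_regime_off: pd.DataFrame | None = None
    latent_regime_on: pd.DataFrame | None = None
    flipped_modules: list = field(default_factory=list)
    marker_of_module: dict = field(default_factory=dict)

    def regime_correlation(self, state: np.ndarray) -> np.ndarray:
        """Latent inter-module correlation matrix for one marker-state vector."""
        n_modules = self.latent_regime_off.shape[0]
        sign = np.ones(n_modules)
        for mod in self.flipped_modules:
            if state[self.marker_of_module[mod]]:
                sign[mod] = -1.0
        base = (
            self.latent_regime_on if np.any(state) and self.flipped_modules
            else self.latent_regime_off
        )
        return np.abs(base.to_numpy()) * np.outer(sign, sign)


def _n_flipped_modules(n_modules: int, switch_effect: float) -> int:
    """Smallest k whose flipped-pair fraction k(M-k)/C(M,2) is closest to target."""
    if n_modules < 2:
        return 0
    n_pairs = n_modules * (n_modules - 1) / 2
    ks = np.arange(0, n_modules // 2 + 1)
    frac = ks * (n_modules - ks) / n_pairs
    return int(ks[np.argmin(np.abs(frac - switch_effect))])


def _mixture_components(spec: SyntheticSpec):
    """Beta mixture components and their CDFs on a fixed grid."""
    kappa = spec.mode_concentration
    (lo, hi) = spec.beta_modes
    a1, b1 = lo * kappa, (1 - lo) * kappa
    a2, b2 = hi * kappa, (1 - hi) * kappa
    grid = np.linspace(0.0, 1.0, 4001)
    cdf_lo = stats.beta.cdf(grid, a1, b1)
    cdf_hi = stats.beta.cdf(grid, a2, b2)
    return grid, cdf_lo, cdf_hi, (a1, b1), (a2, b2)


def _hermite_coefficients(qmaps: list, n_coef: int = 15) -> np.ndarray:
    """Hermite expansion of each probe's latent-to-beta map.

    Writing probe p's map as g_p(x) = sum_k d_pk He_k(x)/sqrt(k!) (He_k the
    probabilists' Hermite polynomials, orthonormal under N(0,1)) gives the
    exact covariance between any two transformed probes whose latents are
    bivariate normal with correlation r:

        Cov(g_p(x), g_q(y)) = sum_{k>=1} d_pk d_qk r^k

    which is how the generator predicts the *beta-scale* module
    correlations its latent regimes will produce.
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(128)
    wts = wts / np.sqrt(2 * np.pi)
    basis = np.empty((n_coef, len(nodes)))
    basis[0] = 1.0
    if n_coef > 1:
        basis[1] = nodes
    for k in range(2, n_coef):
        basis[k] = nodes * basis[k - 1] - (k - 1) * basis[k - 2]
    norms = np.sqrt([float(math.factorial(k)) for k in range(n_coef)])
    coefs = np.empty((len(qmaps), n_coef))
    for p, g in enumerate(qmaps):
        vals = g(nodes)
        coefs[p] = (basis * vals * wts).sum(axis=1) / norms
    return coefs


def _expected_meta_correlation(
    coefs: np.ndarray,
    module_slices: list,
    rho_latent: np.ndarray,
    w_mod: float,
    w_loc: float,
    positions: np.ndarray,
    decay_lambda: float,
) -> np.ndarray:
    """Expected modules x modules meta-profile correlation on the beta scale.

    Within-module probe-pair latent correlation is w_mod + w_loc
    exp(-d/lambda); cross-module pairs have w_mod * rho_ij (the local
    field is negligible across module boundaries).  The Hermite expansion
    turns these latent correlations into beta-scale covariances exactly.
    """
    M = len(module_slices)
    ks = np.arange(coefs.shape[1])
    out = np.eye(M)
    variances = np.empty(M)
    for i, sl in enumerate(module_slices):
        c = coefs[sl]
        pos = positions[sl]
        r_within = w_mod + w_loc * np.exp(
            -np.abs(pos[:, None] - pos[None, :]) / decay_lambda
        )
        np.fill_diagonal(r_within, 1.0)
        rpow = r_within[:, :, None] ** ks[1:]
        variances[i] = float(np.einsum("pk,qk,pqk->", c[:, 1:], c[:, 1:], rpow))
    for i in range(M):
        for j in range(i + 1, M):
            r = w_mod * rho_latent[i, j]
            cov = float(
                np.einsum(
                    "pk,qk->",
                    coefs[module_slices[i], 1:],
                    coefs[module_slices[j], 1:] * (r ** ks[1:])[None, :],
                )
            )
            out[i, j] = out[j, i] = cov / np.sqrt(variances[i] * variances[j])
    return out


def _draw_marker_betas(rng, state_row, comp_lo, comp_hi, mislabel_rate):
    """State-faithful marker values: on => beta >= 0.2, off => beta < 0.2."""
    effective = state_row.copy()
    if mislabel_rate > 0:
        flips = rng.random(len(state_row)) < mislabel_rate
        effective = effective ^ flips
    a1, b1 = comp_lo
    a2, b2 = comp_hi
    cut_lo = stats.beta.cdf(MARKER_STATE_CUTOFF, a1, b1)
    cut_hi = stats.beta.cdf(MARKER_STATE_CUTOFF, a2, b2)
    u = rng.random(len(state_row))
    vals = np.empty(len(state_row))
    on = effective
    vals[on] = stats.beta.ppf(cut_hi + u[on] * (1 - cut_hi), a2, b2)
    vals[~on] = stats.beta.ppf(u[~on] * cut_lo, a1, b1)
    vals[on] = np.clip(vals[on], MARKER_STATE_CUTOFF, 1.0)
    vals[~on] = np.minimum(vals[~on], MARKER_STATE_CUTOFF - 1e-9)
    return np.clip(vals, 0.0, 1.0)


def generate(spec: SyntheticSpec) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Generate (BetaMatrix, probe annotation, GroundTruth) from a spec.

    Fully reproducible under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    M, P = spec.n_modules, spec.probes_per_module
    n_struct = spec.n_module_probes + spec.n_noise_probes
    n_probes, n_samples = spec.n_probes, spec.n_samples

    probe_ids = (
        [f"cg_m{m:02d}_{i:02d}" for m in range(M) for i in range(P)]
        + [f"cg_noise{i:04d}" for i in range(spec.n_noise_probes)]
        + [f"cg_marker{i}" for i in range(spec.n_markers)]
    )
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    positions = 1 + spec.chromosome_layout * np.arange(n_probes)

    # -- marker states and regimes ----------------------------------------
    states = rng.random((spec.n_markers, n_samples)) < spec.methylated_fraction

    def equicorr(rho: float) -> np.ndarray:
        return np.full((M, M), rho) + (1 - rho) * np.eye(M)

    R0 = equicorr(spec.base_correlation) if M else np.zeros((0, 0))
    k_flip = _n_flipped_modules(M, spec.switch_effect) if spec.n_markers else 0
    flipped = list(range(k_flip))
    marker_of_module = {
        mod: j % spec.n_markers for j, mod in enumerate(flipped)
    } if spec.n_markers else {}

    # the "on" regime strengthens inter-module co-methylation to
    # on_correlation and negates the flipped modules; with no flipped
    # modules there is no regime change at all
    sign_all_on = np.ones(M)
    sign_all_on[flipped] = -1.0
    if M and k_flip:
        R_on = equicorr(spec.on_correlation) * np.outer(sign_all_on, sign_all_on)
    else:
        R_on = R0.copy()

    # -- latent module activations: explicit one-factor construction ------
    # z_m = d_m (sqrt(rho) g + sqrt(1-rho) eta_m), which realises the
    # equicorrelation regime exactly; g is the shared "methylator" factor,
    # rho and the sign vector d depend on the sample's regime
    any_on = np.zeros(n_samples, dtype=bool)
    g_factor = rng.standard_normal(n_samples)
    Z = np.zeros((M, n_samples))
    if M:
        sign = np.ones((M, n_samples))
        shift = np.zeros((M, n_samples))
        for mod in flipped:
            on = states[marker_of_module[mod]]
            sign[mod, on] = -1.0
            shift[mod, on] = spec.state_mean_shift
            any_on |= on
        eta = rng.standard_normal((M, n_samples))
        rho = np.where(any_on & (k_flip > 0), spec.on_correlation, spec.base_correlation)
        Z = sign * (np.sqrt(rho) * g_factor + np.sqrt(1.0 - rho) * eta) + shift

    # -- local Ornstein-Uhlenbeck field along the chromosome --------------
    if n_struct:
        pos_struct = positions[:n_struct].astype(float)
        K = np.exp(-np.abs(pos_struct[:, None] - pos_struct[None, :]) / spec.decay_lambda)
        Lk = np.linalg.cholesky(K + 1e-10 * np.eye(n_struct))
        f_field = Lk @ rng.standard_normal((n_struct, n_samples))
    else:
        f_field = np.zeros((0, n_samples))

    eps = rng.standard_normal((n_struct, n_samples))

    latent = np.empty((n_struct, n_samples))
    w_mod, w_loc = spec.module_weight, spec.local_weight
    w_eps = 1.0 - w_mod - w_loc
    for m in range(M):
        rows = slice(m * P, (m + 1) * P)
        latent[rows] = (
            np.sqrt(w_mod) * Z[m]
            + np.sqrt(w_loc) * f_field[rows]
            + np.sqrt(w_eps) * eps[rows]
        )
    # unstructured probes join the shared factor only in the on regime
    w_nloc = spec.noise_local_weight
    w_g = np.where(any_on & (k_flip > 0), spec.noise_on_coupling, 0.0)
    noise_rows = slice(spec.n_module_probes, n_struct)
    latent[noise_rows] = (
        np.sqrt(w_g) * g_factor
        + np.sqrt(w_nloc) * f_field[noise_rows]
        + np.sqrt(1.0 - w_nloc - w_g) * eps[noise_rows]
    )

    # -- latent -> beta via per-probe bimodal mixture quantile maps -------
    # each structured probe gets its own upper-mode mass w_p, so probes
    # differ in typical methylation level as real CpG sites do
    grid, cdf_lo, cdf_hi, comp_lo, comp_hi = _mixture_components(spec)
    a = spec.mode_weight_alpha
    klass = rng.random(n_struct)
    p_var = spec.variable_fraction
    weights = np.where(
        klass < p_var,
        rng.beta(a, a, size=n_struct),
        np.where(
            klass < p_var + (1 - p_var) / 2,
            rng.beta(1.0, 19.0, size=n_struct),
            rng.beta(19.0, 1.0, size=n_struct),
        ),
    )
    betas = np.empty((n_probes, n_samples))
    u_struct = np.clip(stats.norm.cdf(latent), 1e-12, 1 - 1e-12)
    cdfs = (1 - weights)[:, None] * cdf_lo[None, :] + weights[:, None] * cdf_hi[None, :]
    for p in range(n_struct):
        betas[p] = np.interp(u_struct[p], cdfs[p], grid)
    for i in range(spec.n_markers):
        betas[n_struct + i] = _draw_marker_betas(
            rng, states[i], comp_lo, comp_hi, spec.marker_mislabel_rate
        )

    if spec.null_rate > 0:
        nulls = rng.random((n_probes, n_samples)) < spec.null_rate
        betas[nulls] = np.nan

    frame = pd.DataFrame(betas, index=probe_ids, columns=sample_ids)
    matrix = BetaMatrix(frame)

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": "1",
            "position": positions,
            "gene_symbol": [f"GENE{i}" for i in range(n_probes)],
        }
    ).set_index("probe_id", drop=False)

    membership = np.full(n_probes, -1)
    for m in range(M):
        membership[m * P : (m + 1) * P] = m
    if M:
        qmaps = [
            (lambda cdf: (lambda x: np.interp(
                np.clip(stats.norm.cdf(x), 1e-12, 1 - 1e-12), cdf, grid
            )))(cdfs[p])
            for p in range(spec.n_module_probes)
        ]
        coefs = _hermite_coefficients(qmaps)
        slices = [slice(m * P, (m + 1) * P) for m in range(M)]
        meta_off = _expected_meta_correlation(
            coefs, slices, R0, spec.module_weight, spec.local_weight,
            positions[: spec.n_module_probes].astype(float), spec.decay_lambda,
        )
        meta_on = _expected_meta_correlation(
            coefs, slices, R_on, spec.module_weight, spec.local_weight,
            positions[: spec.n_module_probes].astype(float), spec.decay_lambda,
        )
    else:
        meta_off = meta_on = np.zeros((0, 0))
    truth = GroundTruth(
        marker_probe_ids=probe_ids[n_struct:],
        module_membership=pd.Series(membership, index=probe_ids),
        marker_states=pd.DataFrame(
            states, index=probe_ids[n_struct:], columns=sample_ids
        ),
        regime_off=pd.DataFrame(meta_off),
        regime_on=pd.DataFrame(meta_on),
        latent_regime_off=pd.DataFrame(R0),
        latent_regime_on=pd.DataFrame(R_on),
        flipped_modules=flipped,
        marker_of_module=marker_of_module,
    )
    return matrix, annotation, truth


# 20 probes x 60 samples with a deliberately strong constructed effect
# (tight modules, high inter-module correlation, 2 of 4 modules flipped)
# so the planted marker attains the top score at this tiny size
WORKED_EXAMPLE_SPEC = SyntheticSpec(
    n_samples=60,
    n_modules=4,
    probes_per_module=4,
    n_noise_probes=3,
    n_markers=1,
    switch_effect=0.667,
    base_correlation=0.7,
    module_weight=0.85,
    methylated_fraction=0.4,
    null_rate=0.02,
    seed=12345,
)


def worked_example_small() -> tuple[BetaMatrix, pd.DataFrame]:
    """Fixed 20-probe x 60-sample instance with its expected score table.

    The expected scores are computed at call time by the
    straight-from-the-definition reference scorer
    (:mod:`ccrscan.reference`), which shares no code with the pipeline,
    using the planted module structure (noise probes and the marker as
    singleton modules).  The planted marker attains the top score by
    construction.
    """
    from .reference import score_candidates_reference

    matrix, _, truth = generate(WORKED_EXAMPLE_SPEC)
    labels = ground_truth_module_labels(truth)
    expected = score_candidates_reference(matrix.data, labels.to_numpy())
    return matrix, expected


def marker_recovery_spec(seed: int = 0) -> SyntheticSpec:
    """Stated world for planted-marker recovery studies.

    300 samples, 8 modules x 25 probes, 100 unstructured probes and one
    switch marker flipping half the module pairs, with the marker on in
    40% of samples.
    """
    return SyntheticSpec(
        n_samples=300,
        n_modules=8,
        probes_per_module=25,
        n_noise_probes=100,
        n_markers=1,
        switch_effect=0.5,
        methylated_fraction=0.4,
        seed=seed,
    )


def two_regime_spec(seed: int = 0) -> SyntheticSpec:
    """Stated world for two-subtype recovery by value-based clustering.

    Same layout as :func:`marker_recovery_spec`, but the on regime is a
    fully penetrant CIMP-like subtype: the maximal set of module pairs
    flips (switch_effect 0.571 = 16/28 pairs for 8 modules) and the
    flipped modules are strongly hypermethylated when the marker is on
    (latent shift 5), so sample values — not only correlations —
    separate the two regimes, as they do between real cancer subtypes.
    The off regime has independent modules and minimal global coupling.
    """
    return SyntheticSpec(
        n_samples=300,
        n_modules=8,
        probes_per_module=25,
        n_noise_probes=100,
        n_markers=1,
        switch_effect=0.571,
        methylated_fraction=0.4,
        state_mean_shift=5.0,
        base_correlation=0.0,
        noise_on_coupling=0.1,
        seed=seed,
    )


def distance_decay_spec(seed: int = 0) -> SyntheticSpec:
    """Stated world for the correlation-vs-distance analysis.

    One synthetic chromosome of 300 unstructured probes at 100-bp spacing
    whose only structure is the local field with decay length 500 bp,
    weighted strongly (0.8) to emulate the tight co-methylation of
    neighbouring CpG sites.
    """
    return SyntheticSpec(
        n_samples=300,
        n_modules=0,
        probes_per_module=0,
        n_noise_probes=300,
        n_markers=0,
        noise_local_weight=0.8,
        noise_on_coupling=0.0,
        seed=seed,
    )


def ground_truth_module_labels(truth: GroundTruth) -> pd.Series:
    """Planted modules, with every non-member probe as its own singleton."""
    labels = truth.module_membership.copy()
    n_planted = int(labels.max()) + 1 if (labels >= 0).any() else 0
    next_idx = n_planted
    out = labels.to_numpy().copy()
    for i, v in enumerate(out):
        if v < 0:
            out[i] = next_idx
            next_idx += 1
    return pd.Series(out, index=labels.index)
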