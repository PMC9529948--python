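"""Synthetic cohorts with known ground truth.

The study design this emulates: three bounded graduate-school cohorts
(~275-285 students each) answer a roster friendship survey; an imaged
subsample (n = 112 across cohorts) contributes one mean-FA value per
white-matter tract, with tracts grouped into four social-processing brain
networks (affective 33, face perception 50, mentalizing 41, mirroring 49
tracts).  The generator plants a known linear mapping from one transformed
network-position metric into a chosen subset of tracts, plus covariate
confounding and Gaussian noise, so every downstream stage can be tested
against ground truth.

Edge model: each unordered pair seeds a nomination with probability
proportional to the geometric mean of gamma-distributed sociability
propensities (right-skewed degree distributions); a seeded edge is
reciprocated with probability psi = rho / (2 - rho), which makes the
expected edge-level reciprocity equal the target rho.  This is the
simplest mechanism hitting the printed density and reciprocity levels,
not a claim about real friendship formation.

FA model, for imaged subject i and tract t:

    FA[i, t] = baseline + offset_t + b_t * y_i + gamma_t' z_i + sigma eps,

clipped to [0.1, 0.9], where y is the standardized transformed effect
metric, b_t is nonzero only for designated signal tracts and scaled so the
planted linear combination explains ``effect_r2`` of the outcome variance,
and z_i are (standardized) age, gender and extraversion covariates.  The
noise ``eps`` has a subject-level component shared across tracts (FA is
strongly correlated between tracts within a subject in real data) plus an
idiosyncratic part; ``fa_noise_sd`` is the total per-tract noise sd and
``fa_noise_correlation`` the between-tract noise correlation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .features import TractFeatureMatrix
from .graph import DirectedCohortGraph, position_profiles, transform_metrics

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "substream",
    "generate_cohort_graph",
    "generate_fa_matrix",
    "simulate_cohorts",
    "generate_dataset",
]

#: Tract counts per network in the tractography-defined study design.
DEFAULT_TRACT_COUNTS = {"affective": 33, "face": 50, "mentalizing": 41,
                        "mirroring": 49}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a single global seed.

    Streams are derived from (seed, crc32(name)) so modules can regenerate
    their piece of a dataset independently of generation order.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode()) % 2**31])
    )


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults reproduce the study's conditions.

    ``cohort_sizes``, ``imaged_per_cohort``, ``target_mean_degree`` and
    ``target_reciprocity`` are per-cohort tuples; degree targets count
    incoming plus outgoing ties per node.
    """

    cohort_sizes: tuple = (275, 279, 285)
    imaged_per_cohort: tuple = (46, 32, 34)
    tract_counts: dict = field(default_factory=lambda: dict(DEFAULT_TRACT_COUNTS))
    target_mean_degree: tuple = (91.0, 78.0, 55.0)
    target_reciprocity: tuple = (0.53, 0.49, 0.48)
    effect_metric: str = "eigenvector"
    effect_network: str = "mirroring"
    effect_r2: float = 0.2
    signal_sparsity: float = 0.5
    covariate_confounding: float = 0.3
    fa_noise_sd: float = 0.03
    fa_noise_correlation: float = 0.5
    fa_baseline: float = 0.45
    tract_offset_sd: float = 0.05
    covariate_loading_sd: float = 0.01
    sociability_shape: float = 4.0
    seed: int = 0

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    @property
    def imaged_n(self) -> int:
        return int(sum(self.imaged_per_cohort))

    def validate(self):
        if not 0 <= self.effect_r2 < 1:
            raise ValueError("effect_r2 must lie in [0, 1)")
        if not 0 < self.signal_sparsity <= 1:
            raise ValueError("signal_sparsity must lie in (0, 1]")
        if any(c < 1 for c in self.tract_counts.values()):
            raise ValueError("tract counts must be >= 1")
        if len(self.imaged_per_cohort) != self.n_cohorts:
            raise ValueError("imaged_per_cohort must match cohort_sizes")
        for m, n in zip(self.imaged_per_cohort, self.cohort_sizes):
            if m > n:
                raise ValueError("imaged subjects cannot exceed cohort size")
        for i in range(self.n_cohorts):
            rho = self.target_reciprocity[i]
            d = self.target_mean_degree[i]
            if not 0 <= rho <= 1:
                raise ValueError(f"cohort {i}: reciprocity target {rho} outside [0, 1]")
            if not 0 < d < 2 * (self.cohort_sizes[i] - 1):
                raise ValueError(f"cohort {i}: infeasible mean total degree {d}")
        if self.effect_r2 > 0 and self.effect_network not in self.tract_counts:
            raise ValueError(
                f"effect network {self.effect_network!r} has no tracts"
            )

    def replace(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)

    @classmethod
    def null(cls, **kw) -> "SyntheticSpec":
        """A no-signal, no-confounding configuration (calibration runs)."""
        return cls(effect_r2=0.0, covariate_confounding=0.0, **kw)


@dataclass
class GroundTruth:
    """What was planted: per-tract signal weights, the latent outcome, and
    the covariate table, recorded alongside every generated dataset."""

    signal_weights: pd.Series
    latent_outcome: pd.Series
    covariate_table: pd.DataFrame

    def to_tsv(self, path):
        side = self.signal_weights.rename("signal_weight").to_frame()
        side.index.name = "tract"
        side.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class SyntheticDataset:
    """One generated imaging-arm dataset plus its provenance."""

    spec: SyntheticSpec
    graphs: dict
    metrics_raw: pd.DataFrame          # full-cohort raw metrics
    metrics_transformed: pd.DataFrame  # imaged subsample, transformed
    features: TractFeatureMatrix
    covariates: pd.DataFrame
    truth: GroundTruth

    def outcome(self, metric: str) -> pd.Series:
        """Transformed outcome vector aligned to the feature matrix."""
        y = self.metrics_transformed[metric]
        return y.loc[self.features.subject_ids]


def generate_cohort_graph(spec: SyntheticSpec, cohort_index: int,
                          seed=None) -> DirectedCohortGraph:
    """One cohort's directed friendship graph hitting the density targets.

    Realized mean total degree and reciprocity land within a few percent of
    the targets at the study's cohort sizes; a gamma-distributed
    sociability propensity per subject induces right-skewed degrees.
    """
    spec.validate()
    n = int(spec.cohort_sizes[cohort_index])
    rho = float(spec.target_reciprocity[cohort_index])
    d = float(spec.target_mean_degree[cohort_index])
    rng = substream(spec.seed if seed is None else seed,
                    f"graph-cohort-{cohort_index}")

    psi = rho / (2.0 - rho)  # reciprocation prob: edge reciprocity = 2psi/(1+psi)
    p_pair = d / ((n - 1) * (1.0 + psi))
    # correct for E[sqrt(s_i s_j)] < 1 under gamma propensities
    k = spec.sociability_shape
    mean_sqrt = np.exp(gammaln(k + 0.5) - gammaln(k)) / np.sqrt(k)
    p_pair /= mean_sqrt**2

    s = rng.gamma(shape=k, scale=1.0 / k, size=n)
    iu, ju = np.triu_indices(n, k=1)
    p = np.clip(p_pair * np.sqrt(s[iu] * s[ju]), 0.0, 1.0)
    seeded = rng.random(p.size) < p
    forward = rng.random(p.size) < 0.5  # direction of the seeding nomination
    recip = rng.random(p.size) < psi

    ids = [f"c{cohort_index + 1}s{j:03d}" for j in range(n)]
    edges = set()
    for a, b, fwd, rec in zip(iu[seeded], ju[seeded], forward[seeded],
                              recip[seeded]):
        ego, alter = (a, b) if fwd else (b, a)
        edges.add((ids[ego], ids[alter]))
        if rec:
            edges.add((ids[alter], ids[ego]))
    return DirectedCohortGraph(cohort_id=f"cohort{cohort_index + 1}",
                               nodes=ids, edges=edges)


def simulate_cohorts(spec: SyntheticSpec, seed=None):
    """All cohort graphs plus their full-roster raw metric tables.

    Computing the graph metrics once here lets many imaging-arm replicates
    (fresh FA matrices, fresh imaged subsamples) reuse the same cohorts,
    exactly as one survey wave serves every downstream analysis.
    """
    spec.validate()
    graphs = {}
    tables = []
    for i in range(spec.n_cohorts):
        g = generate_cohort_graph(spec, i, seed=seed)
        graphs[g.cohort_id] = g
        tables.append(position_profiles(g))
    return graphs, pd.concat(tables)


def _tract_ids(spec: SyntheticSpec) -> list:
    return [f"{net}::t{j:02d}" for net, cnt in spec.tract_counts.items()
            for j in range(cnt)]


def generate_fa_matrix(graphs: dict, spec: SyntheticSpec, seed=None,
                       metrics_raw: pd.DataFrame | None = None):
    """FA feature matrix for an imaged subsample, with planted signal.

    Returns ``(features, truth)``; use :func:`generate_dataset` for the
    full bundle including covariates and the transformed metric table.
    """
    ds = _generate_imaging(graphs, spec, seed=seed, metrics_raw=metrics_raw)
    return ds.features, ds.truth


def _generate_imaging(graphs: dict, spec: SyntheticSpec, seed=None,
                      metrics_raw: pd.DataFrame | None = None) -> SyntheticDataset:
    spec.validate()
    base_seed = spec.seed if seed is None else seed
    rng = substream(base_seed, "imaging")

    if metrics_raw is None:
        metrics_raw = pd.concat([position_profiles(g) for g in graphs.values()])

    # imaged subsample, without replacement, fixed count per cohort
    cohort_ids = sorted(graphs)
    imaged = []
    for cid, m in zip(cohort_ids, spec.imaged_per_cohort):
        members = metrics_raw.index[metrics_raw["cohort"] == cid].to_numpy()
        if len(members) < m:
            raise ValueError(f"cohort {cid!r} smaller than imaged count {m}")
        imaged.extend(rng.choice(members, size=m, replace=False))
    imaged = list(imaged)

    metrics_imaged = metrics_raw.loc[imaged]
    transformed = transform_metrics(metrics_imaged)

    # latent outcome: the chosen transformed metric, scaled to unit variance
    y = transformed[spec.effect_metric].to_numpy(dtype=float)
    if np.isnan(y).any():
        # isolates (undefined constraint) cannot carry the planted signal
        keep = ~np.isnan(y)
        raise ValueError(
            f"effect metric {spec.effect_metric!r} undefined for "
            f"{int((~keep).sum())} imaged subject(s); choose another metric "
            "or denser networks"
        )
    y_std = (y - y.mean()) / y.std()

    # covariates
    n = len(imaged)
    age = rng.integers(24, 36, size=n)
    gender = rng.choice(["female", "male"], size=n, p=[0.36, 0.64])
    handed = rng.choice(["right", "left"], size=n, p=[0.9, 0.1])
    c = float(spec.covariate_confounding)
    ext_noise = rng.standard_normal(n)
    if abs(c) < 1:
        extraversion = c * y_std + np.sqrt(1 - c**2) * ext_noise
    else:
        extraversion = np.sign(c) * y_std
    covariates = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "handedness": handed,
            "cohort": metrics_imaged["cohort"].to_numpy(),
            "extraversion": extraversion,
        },
        index=pd.Index(imaged, name="subject_id"),
    )

    # tract structure and planted weights
    tracts = _tract_ids(spec)
    t_count = len(tracts)
    offsets = rng.normal(0.0, spec.tract_offset_sd, size=t_count)
    weights = np.zeros(t_count)
    if spec.effect_r2 > 0:
        net_cols = [k for k, t in enumerate(tracts)
                    if t.startswith(spec.effect_network + "::")]
        if not net_cols:
            raise ValueError("no tracts available to carry the planted signal")
        k_sig = max(1, int(round(spec.signal_sparsity * len(net_cols))))
        sig_cols = rng.choice(net_cols, size=k_sig, replace=False)
        sigma = spec.fa_noise_sd if spec.fa_noise_sd > 0 else 0.01
        b = sigma * np.sqrt(spec.effect_r2 / ((1 - spec.effect_r2) * k_sig))
        weights[sig_cols] = rng.choice([-1.0, 1.0], size=k_sig) * b

    # covariate loadings into FA (confounding path)
    age_std = (age - age.mean()) / max(age.std(), 1e-12)
    gender_num = (gender == "female").astype(float)
    gender_std = gender_num - gender_num.mean()
    loadings = rng.normal(0.0, spec.covariate_loading_sd, size=(3, t_count)) * c
    cov_term = (np.column_stack([age_std, gender_std, extraversion]) @ loadings)

    # tract noise: a subject-level shared factor (global white-matter
    # integrity / motion / scanner effects make FA strongly correlated
    # across tracts in real data) plus an idiosyncratic part; the total
    # per-tract noise variance is fa_noise_sd^2 and the between-tract noise
    # correlation is fa_noise_correlation.
    rho_n = float(spec.fa_noise_correlation)
    if not 0 <= rho_n < 1:
        raise ValueError("fa_noise_correlation must lie in [0, 1)")
    shared_sd = spec.fa_noise_sd * np.sqrt(rho_n)
    idio_sd = spec.fa_noise_sd * np.sqrt(1.0 - rho_n)
    noise = (shared_sd * rng.standard_normal((n, 1))
             + idio_sd * rng.standard_normal((n, t_count)))
    fa = (spec.fa_baseline + offsets[None, :] + np.outer(y_std, weights)
          + cov_term + noise)
    fa = np.clip(fa, 0.1, 0.9)

    features = TractFeatureMatrix(
        pd.DataFrame(fa, index=pd.Index(imaged, name="subject_id"),
                     columns=tracts)
    )
    truth = GroundTruth(
        signal_weights=pd.Series(weights, index=tracts, name="signal_weight"),
        latent_outcome=pd.Series(y_std, index=features.values.index,
                                 name="latent_outcome"),
        covariate_table=covariates,
    )
    return SyntheticDataset(
        spec=spec, graphs=graphs, metrics_raw=metrics_raw,
        metrics_transformed=transformed, features=features,
        covariates=covariates, truth=truth,
    )


def generate_dataset(spec: SyntheticSpec, seed=None,
                     cohorts=None) -> SyntheticDataset:
    """Generate a complete dataset (graphs, metrics, FA, covariates, truth).

    Pass ``cohorts=(graphs, metrics_raw)`` from :func:`simulate_cohorts`
    to reuse the survey arm across imaging replicates; ``seed`` overrides
    ``spec.seed`` for the imaging arm only in that case.
    """
    if cohorts is None:
        graphs, metrics_raw = simulate_cohorts(spec, seed=seed)
    else:
        graphs, metrics_raw = cohorts
    return _generate_imaging(graphs, spec, seed=seed, metrics_raw=metrics_raw)
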