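"""Synthetic dual-transcriptome data with known ground truth.

Emulates a crossed host-genotype x fungal-genotype greenhouse experiment
(five cassava cultivars x {two AMF isolates, mock}) after in-silico read
separation: one count matrix per organism over a shared sample set, a
sample metadata table, quantitative growth traits, and the planted truth
(module labels, per-gene response classes, cross-organism factor links,
trait loadings).

The generative model is a log-linear negative-binomial factor model:
each planted module has one latent factor per sample; factors carry
cultivar main effects, treatment main effects and cultivar x treatment
interaction effects according to the module's response class;
cross-linked host/symbiont module pairs share a common factor component.
Gene means are ``exp(baseline + loading * factor)`` scaled to the sample
library size, and counts are drawn gamma-Poisson (negative binomial).
Symbiont counts in mock samples are sparse contamination, mirroring the
near-zero fungal transcript recovery from non-inoculated roots.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .containers import CountMatrix

__all__ = [
    "MOCK_LEVEL",
    "DEFAULT_CULTIVARS",
    "SimConfig",
    "SimTruth",
    "SimData",
    "generate_design",
    "generate_latent_factors",
    "generate_counts",
    "generate_traits",
    "simulate_dataset",
    "write_dataset",
]

MOCK_LEVEL = "mock"

# Cultivar codes of the motivating experiment; used when n_cultivars == 5.
DEFAULT_CULTIVARS = ("CM6438-14", "COL2215", "BRA337", "CM4574-7", "CM523-7")

RESPONSE_CLASSES = (
    "cultivar_only",
    "mycorrhiza_conserved",
    "isolate_conserved",
    "interaction",
    "null",
)

# Default planted classes per module, cycled. Host modules default to
# AMF-responsive classes so they survive the differential-expression
# pool filter applied before host module construction. No two modules
# of one network share the same binary design contrast: two factors on
# an identical contrast are collinear up to noise, so their "modules"
# would be a single module in truth. Interaction modules stay mutually
# distinguishable because each draws its own random cell pattern.
# Cross-linked modules (defaults link the first three pairs) carry
# classes whose factors vary across inoculated samples: a
# mycorrhiza-conserved factor is nearly constant there, so a cross-link
# anchored on it would be unobservable in the subset where both
# organisms exist. The conserved module is planted unlinked (host M4).
_DEFAULT_HOST_MODULE_CLASSES = (
    "interaction",
    "interaction",
    "isolate_conserved",
    "mycorrhiza_conserved",
    "interaction",
)
_DEFAULT_SYM_MODULE_CLASSES = (
    "cultivar_only",
    "interaction",
    "cultivar_only",
    "interaction",
    "cultivar_only",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic dual dataset.

    Defaults describe a desk-scale version of the motivating design:
    5 cultivars x (2 isolates + mock) x 3 replicates = 45 samples,
    2500 genes per organism of which five modules of 60-100 genes are
    planted (the rest carry individual responses or no signal), three
    cross-organism module links of strength 0.9, and a
    colonization-like trait loaded on the first linked pair.
    """

    n_cultivars: int = 5
    n_fungal_levels: int = 3
    n_reps: int = 3
    n_blocks: int = 3

    host_n_genes: int = 2500
    sym_n_genes: int = 2500
    host_module_sizes: Sequence[int] = (100, 90, 80, 70, 60)
    sym_module_sizes: Sequence[int] = (100, 90, 80, 70, 60)
    host_module_classes: Sequence[str] | None = None
    sym_module_classes: Sequence[str] | None = None

    # (host module, symbiont module, sign, strength in [0, 1]);
    # modules are numbered from 1.
    cross_links: Sequence[tuple[int, int, int, float]] = (
        (1, 1, +1, 0.9),
        (2, 2, -1, 0.9),
        (3, 3, +1, 0.9),
    )

    within_module_cor: float = 0.6
    effect_strength: float = 0.6  # share of factor variance from design effects
    # signal share of genes with an individual (non-module) planted
    # response; weaker than module genes, mimicking the long tail of
    # subtle effects in real transcriptomes
    free_gene_signal: float = 0.15
    # latent per-sample nuisance factors (tissue composition, library
    # quality, read-separation artifacts): organism-specific axes with
    # random per-gene loadings, the "unwanted variation" of RNA-seq
    n_nuisance_factors: int = 3
    nuisance_signal: float = 0.25  # share of a null gene's log-scale variance
    gxg_fraction: float = 0.10
    cultivar_fraction: float = 0.10
    conserved_fraction: float = 0.10

    nb_dispersion: float = 0.2
    baseline_log_sd: float = 1.2
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    contamination_rate: float = 0.1  # mean mock symbiont counts per gene

    # (factor name e.g. "host_M1", trait name, coefficient)
    trait_loadings: Sequence[tuple[str, str, float]] = (
        ("host_M1", "colonization", 1.0),
        ("sym_M1", "colonization", 0.5),
        ("host_M2", "plant_dry_weight", 0.8),
        ("sym_M2", "hyphal_density", 0.8),
    )
    trait_noise_sd: float = 0.3
    colonization_trait: str = "colonization"
    colonization_center: float = 0.4
    colonization_scale: float = 0.12

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cultivars", "n_fungal_levels", "n_reps", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for sizes, n in (
            (self.host_module_sizes, self.host_n_genes),
            (self.sym_module_sizes, self.sym_n_genes),
        ):
            if any(s < 1 for s in sizes):
                raise ValueError("module sizes must be >= 1")
            if sum(sizes) > n:
                raise ValueError("module sizes exceed gene count")
        for _, _, sign, strength in self.cross_links:
            if sign not in (-1, 1):
                raise ValueError("cross-link sign must be +1 or -1")
            if not 0.0 <= strength <= 1.0:
                raise ValueError("cross-link strength must be in [0, 1]")
        frac = self.gxg_fraction + self.cultivar_fraction + self.conserved_fraction
        if frac > 1.0 + 1e-12:
            raise ValueError("planted response-class fractions must sum to <= 1")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in (0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def module_classes(self, organism: str) -> list[str]:
        if organism == "host":
            given, n = self.host_module_classes, len(self.host_module_sizes)
            default = _DEFAULT_HOST_MODULE_CLASSES
        else:
            given, n = self.sym_module_classes, len(self.sym_module_sizes)
            default = _DEFAULT_SYM_MODULE_CLASSES
        if given is not None:
            if len(given) != n:
                raise ValueError("module_classes length must match module_sizes")
            bad = set(given) - set(RESPONSE_CLASSES)
            if bad:
                raise ValueError(f"unknown response class(es): {sorted(bad)}")
            return list(given)
        return [default[i % len(default)] for i in range(n)]


@dataclass
class SimTruth:
    """Planted ground truth emitted by the simulator."""

    module_labels: dict[str, dict[str, int]]  # organism -> gene -> module (0 = none)
    gene_classes: dict[str, dict[str, str]]  # organism -> gene -> response class
    module_classes: dict[str, list[str]]  # organism -> class per planted module
    cross_links: list[tuple[int, int, int, float]]
    trait_loadings: list[tuple[str, str, float]]
    factors: pd.DataFrame | None = None  # sample x factor

    def labels_vector(self, organism: str, gene_ids: Sequence[str]) -> np.ndarray:
        lab = self.module_labels[organism]
        return np.asarray([lab[g] for g in gene_ids], dtype=int)

    def to_dict(self) -> dict:
        d = {
            "module_labels": self.module_labels,
            "gene_classes": self.gene_classes,
            "module_classes": self.module_classes,
            "cross_links": [list(link) for link in self.cross_links],
            "trait_loadings": [list(tl) for tl in self.trait_loadings],
        }
        if self.factors is not None:
            d["factors"] = {
                "samples": list(self.factors.index),
                "names": list(self.factors.columns),
                "values": self.factors.to_numpy().tolist(),
            }
        return d


@dataclass
class SimData:
    """Bundle returned by :func:`simulate_dataset`."""

    design: pd.DataFrame
    host_counts: CountMatrix
    sym_counts: CountMatrix
    traits: pd.DataFrame
    factors: pd.DataFrame
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# design


def _cultivar_names(n: int) -> list[str]:
    if n == len(DEFAULT_CULTIVARS):
        return list(DEFAULT_CULTIVARS)
    return [f"cv{i + 1}" for i in range(n)]


def _treatment_names(n: int) -> list[str]:
    if n == 1:
        return [MOCK_LEVEL]
    if n == 3:
        return ["isolateA", "isolateB", MOCK_LEVEL]
    return [f"isolate{chr(ord('A') + i)}" for i in range(n - 1)] + [MOCK_LEVEL]


def generate_design(
    n_cultivars: int = 5,
    n_fungal_levels: int = 3,
    n_reps: int = 3,
    n_blocks: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial cultivar x fungal-treatment design with replicates.

    Samples are shuffled (seeded) and assigned to blocks round-robin,
    emulating a randomized greenhouse layout. Exactly one treatment
    level is the mock (non-inoculated) control.

    Returns a DataFrame with columns ``sample_id``, ``cultivar``,
    ``fungal_treatment``, ``block``, ``replicate``, indexed by sample_id.
    """
    for name, v in (
        ("n_cultivars", n_cultivars),
        ("n_fungal_levels", n_fungal_levels),
        ("n_reps", n_reps),
        ("n_blocks", n_blocks),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    cultivars = _cultivar_names(n_cultivars)
    treatments = _treatment_names(n_fungal_levels)
    rows = []
    for cv in cultivars:
        for tr in treatments:
            for rep in range(1, n_reps + 1):
                rows.append((cv, tr, rep))
    n = len(rows)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    blocks = np.empty(n, dtype=int)
    blocks[order] = np.arange(n) % n_blocks + 1
    design = pd.DataFrame(
        {
            "sample_id": ids,
            "cultivar": [rows[i][0] for i in range(n)],
            "fungal_treatment": [rows[i][1] for i in range(n)],
            "block": [f"B{b}" for b in blocks],
            "replicate": [rows[i][2] for i in range(n)],
        }
    )
    return design.set_index("sample_id", drop=False)


def inoculated_mask(design: pd.DataFrame) -> pd.Series:
    return design["fungal_treatment"] != MOCK_LEVEL


# ---------------------------------------------------------------------------
# latent factors


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _effect_pattern(
    design: pd.DataFrame, response_class: str, organism: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample design-effect values for one response class.

    For the symbiont the mock level carries no effect (the fungus is
    absent there) and ``mycorrhiza_conserved`` degenerates to
    ``isolate_conserved``.
    """
    cv = design["cultivar"].to_numpy()
    tr = design["fungal_treatment"].to_numpy()
    e = np.zeros(len(design))
    if organism == "symbiont" and response_class == "mycorrhiza_conserved":
        response_class = "isolate_conserved"
    if response_class == "null":
        return e
    if response_class == "cultivar_only":
        levels = pd.unique(cv)
        offsets = dict(zip(levels, rng.normal(0.0, 1.0, len(levels))))
        e = np.asarray([offsets[c] for c in cv])
    elif response_class == "mycorrhiza_conserved":
        d = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        e = np.where(tr == MOCK_LEVEL, -d, d)
    elif response_class == "isolate_conserved":
        iso = [t for t in pd.unique(tr) if t != MOCK_LEVEL]
        offs = rng.uniform(0.5, 1.5, len(iso)) * rng.choice([-1.0, 1.0], len(iso))
        offs -= offs.mean()  # mock sits at the isolate average: no AMF-vs-mock signal
        offsets = dict(zip(iso, offs))
        offsets[MOCK_LEVEL] = 0.0
        e = np.asarray([offsets[t] for t in tr])
    elif response_class == "interaction":
        # random cell offsets, double-centered so the pattern is purely
        # non-additive (no cultivar or treatment main-effect component)
        cv_levels = list(pd.unique(cv))
        tr_levels = [
            t
            for t in pd.unique(tr)
            if not (organism == "symbiont" and t == MOCK_LEVEL)
        ]
        if not tr_levels:
            return e
        cellmat = rng.normal(0.0, 1.0, (len(cv_levels), len(tr_levels)))
        cellmat -= cellmat.mean(axis=1, keepdims=True)
        cellmat -= cellmat.mean(axis=0, keepdims=True)
        offsets = {
            (c, t): cellmat[i, j]
            for i, c in enumerate(cv_levels)
            for j, t in enumerate(tr_levels)
        }
        e = np.asarray([offsets.get((c, t), 0.0) for c, t in zip(cv, tr)])
    else:
        raise ValueError(f"unknown response class {response_class!r}")
    return e


def _module_factor(
    design: pd.DataFrame,
    response_class: str,
    organism: str,
    effect_strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance latent factor: design effect + biological noise."""
    e = _effect_pattern(design, response_class, organism, rng)
    z = rng.normal(0.0, 1.0, len(design))
    if np.allclose(e, 0.0):
        return _standardize(z)
    f = np.sqrt(effect_strength) * _standardize(e) + np.sqrt(
        1.0 - effect_strength
    ) * _standardize(z)
    return _standardize(f)


def generate_latent_factors(
    design: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """One unit-variance latent factor per planted module, both organisms.

    Cross-linked (host, symbiont) module pairs share a common component:
    over inoculated samples the symbiont factor is
    ``sign * (strength * f_host + sqrt(1 - strength^2) * f_own)``, so a
    link of strength 1 makes the two factors identical up to sign.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    host_classes = config.module_classes("host")
    sym_classes = config.module_classes("symbiont")
    n_host = len(config.host_module_sizes)
    n_sym = len(config.sym_module_sizes)
    for hm, sm, _, _ in config.cross_links:
        if not (1 <= hm <= n_host and 1 <= sm <= n_sym):
            raise ValueError(f"cross-link references unknown module pair ({hm}, {sm})")

    cols: dict[str, np.ndarray] = {}
    for i, cls in enumerate(host_classes, start=1):
        cols[f"host_M{i}"] = _module_factor(
            design, cls, "host", config.effect_strength, rng
        )
    for i, cls in enumerate(sym_classes, start=1):
        cols[f"sym_M{i}"] = _module_factor(
            design, cls, "symbiont", config.effect_strength, rng
        )
    # Cross-links are defined over inoculated samples (the fungus does
    # not exist in mock roots), so the mixture is built on the
    # inoculated restriction; mock samples keep the module's own values.
    inoc = inoculated_mask(design).to_numpy()
    for hm, sm, sign, strength in config.cross_links:
        f_h = cols[f"host_M{hm}"]
        f_own = cols[f"sym_M{sm}"]
        mixed = f_own.copy()
        if inoc.any():
            a = _standardize(f_h[inoc])
            b = _standardize(f_own[inoc])
            mixed[inoc] = sign * (strength * a + np.sqrt(1.0 - strength**2) * b)
        cols[f"sym_M{sm}"] = _standardize(mixed)

    factors = pd.DataFrame(cols, index=design.index)
    truth = SimTruth(
        module_labels={},
        gene_classes={},
        module_classes={"host": host_classes, "symbiont": sym_classes},
        cross_links=list(config.cross_links),
        trait_loadings=list(config.trait_loadings),
        factors=factors,
    )
    return factors, truth


# ---------------------------------------------------------------------------
# counts


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with mean ``m`` and variance ``m + a m^2``.

    Gamma-Poisson mixture; collapses to Poisson at dispersion 0.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def _assign_gene_classes(
    n_free: int, config: SimConfig, rng: np.random.Generator
) -> list[str]:
    """Response classes for genes outside planted modules.

    The configured fractions apply here; ``conserved_fraction`` is split
    evenly between the mycorrhiza-conserved and isolate-conserved
    classes. The remainder are null genes.
    """
    n_gxg = int(round(config.gxg_fraction * n_free))
    n_cv = int(round(config.cultivar_fraction * n_free))
    n_cons = int(round(config.conserved_fraction * n_free))
    n_myc = n_cons // 2
    n_iso = n_cons - n_myc
    classes = (
        ["interaction"] * n_gxg
        + ["cultivar_only"] * n_cv
        + ["mycorrhiza_conserved"] * n_myc
        + ["isolate_conserved"] * n_iso
    )
    classes += ["null"] * (n_free - len(classes))
    rng.shuffle(classes)
    return classes


def _organism_counts(
    design: pd.DataFrame,
    factors: pd.DataFrame,
    config: SimConfig,
    organism: str,
    rng: np.random.Generator,
) -> tuple[CountMatrix, dict[str, int], dict[str, str]]:
    if organism == "host":
        n_genes = config.host_n_genes
        sizes = list(config.host_module_sizes)
        classes = config.module_classes("host")
        prefix, fprefix = "h", "host_M"
    else:
        n_genes = config.sym_n_genes
        sizes = list(config.sym_module_sizes)
        classes = config.module_classes("symbiont")
        prefix, fprefix = "f", "sym_M"

    width = max(4, len(str(n_genes)))
    gene_ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n_genes)]
    n_samples = len(design)

    labels = np.zeros(n_genes, dtype=int)
    gene_class = np.empty(n_genes, dtype=object)
    gene_factor = np.full(n_genes, -1, dtype=int)  # column into the factor block

    pos = 0
    for m, (size, cls) in enumerate(zip(sizes, classes), start=1):
        labels[pos : pos + size] = m
        gene_class[pos : pos + size] = cls
        gene_factor[pos : pos + size] = m - 1
        pos += size
    free_classes = _assign_gene_classes(n_genes - pos, config, rng)
    gene_class[pos:] = free_classes

    # Factor value per gene per sample. Module genes share the module
    # factor; non-null free genes get a private pure-effect profile.
    fac_block = factors[[c for c in factors.columns if c.startswith(fprefix)]]
    fac = fac_block.to_numpy()  # samples x modules
    profile = np.zeros((n_genes, n_samples))
    in_module = gene_factor >= 0
    profile[in_module] = fac[:, gene_factor[in_module]].T
    for g in range(pos, n_genes):
        if gene_class[g] != "null":
            e = _effect_pattern(design, gene_class[g], organism, rng)
            profile[g] = _standardize(e)

    # Baselines and loadings. The loading is tuned per gene so that the
    # expected within-module log-CPM correlation matches
    # within_module_cor: rho = lambda^2 / (lambda^2 + sigma^2) with
    # sigma^2 ~ 1/mu + dispersion (delta method on log counts).
    base_log = rng.normal(0.0, config.baseline_log_sd, n_genes)
    rel = np.exp(base_log)
    mean_lib = float(np.mean(config.lib_size_range))
    mu_hat = mean_lib * rel / rel.sum()
    # log-scale counting-noise variance of a gamma-Poisson count:
    # trigamma(1/dispersion) for the gamma mixing + 1/mu Poisson part
    if config.nb_dispersion > 1e-12:
        gamma_var = float(polygamma(1, 1.0 / config.nb_dispersion))
    else:
        gamma_var = 0.0
    sigma2 = 1.0 / np.maximum(mu_hat, 1e-6) + gamma_var

    # organism-specific sample-level nuisance axes with random per-gene
    # loadings; tau^2 is sized so a null gene's log-scale variance is
    # nuisance_signal nuisance vs (1 - nuisance_signal) counting noise
    K = config.n_nuisance_factors
    nu = config.nuisance_signal
    tau2 = sigma2 * nu / (1.0 - nu) if K > 0 and nu > 0 else np.zeros(n_genes)
    if K > 0 and nu > 0:
        H = rng.normal(0.0, 1.0, (K, n_samples))
        U = rng.normal(0.0, 1.0, (n_genes, K)) * np.sqrt(tau2 / K)[:, None]
        nuisance = U @ H
    else:
        nuisance = 0.0

    # module/free loadings sized so the expected within-module log-CPM
    # correlation is rho against the total non-factor variance
    rho_vec = np.where(in_module, config.within_module_cor, config.free_gene_signal)
    lam = np.sqrt((sigma2 + tau2) * rho_vec / (1.0 - rho_vec))
    lam[np.asarray(gene_class) == "null"] = 0.0

    # Fixed-denominator mean model: per-sample expected counts are the
    # baseline share times the factor fold change, so one gene's
    # regulation does not compositionally drag every other gene.
    log_mu = base_log[:, None] + lam[:, None] * profile + nuisance
    shares0 = np.exp(log_mu) / rel.sum()
    lib_sizes = rng.integers(
        config.lib_size_range[0], config.lib_size_range[1] + 1, n_samples
    ).astype(float)
    mu = shares0 * lib_sizes[None, :]
    counts = _nb_sample(rng, mu, config.nb_dispersion)

    if organism == "symbiont":
        mock = (~inoculated_mask(design)).to_numpy()
        if mock.any():
            counts[:, mock] = rng.poisson(
                config.contamination_rate, size=(n_genes, int(mock.sum()))
            )

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=design.index),
        organism=organism,
    )
    label_map = dict(zip(gene_ids, (int(v) for v in labels)))
    class_map = dict(zip(gene_ids, (str(c) for c in gene_class)))
    return cm, label_map, class_map


def generate_counts(
    design: pd.DataFrame,
    factors: pd.DataFrame,
    config: SimConfig,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Draw host and symbiont count matrices from the factor model."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        truth = SimTruth(
            module_labels={},
            gene_classes={},
            module_classes={
                "host": config.module_classes("host"),
                "symbiont": config.module_classes("symbiont"),
            },
            cross_links=list(config.cross_links),
            trait_loadings=list(config.trait_loadings),
            factors=factors,
        )
    host, host_labels, host_classes = _organism_counts(
        design, factors, config, "host", rng
    )
    sym, sym_labels, sym_classes = _organism_counts(
        design, factors, config, "symbiont", rng
    )
    truth.module_labels = {"host": host_labels, "symbiont": sym_labels}
    truth.gene_classes = {"host": host_classes, "symbiont": sym_classes}
    return host, sym, truth


# ---------------------------------------------------------------------------
# traits


def generate_traits(
    design: pd.DataFrame,
    factors: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample x trait table from configured module-factor loadings.

    Each trait is a linear combination of module factors plus Gaussian
    noise. The colonization-like trait is affinely rescaled into [0, 1]
    and forced to exactly 0 for mock samples (no fungus, no
    colonization).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    trait_names: list[str] = []
    for fac, trait, _ in config.trait_loadings:
        if fac not in factors.columns:
            raise ValueError(f"trait loading references unknown module factor {fac!r}")
        if trait not in trait_names:
            trait_names.append(trait)
    out = pd.DataFrame(index=design.index)
    for trait in trait_names:
        lin = np.zeros(len(design))
        for fac, t, coef in config.trait_loadings:
            if t == trait:
                lin = lin + coef * factors[fac].to_numpy()
        lin = lin + rng.normal(0.0, config.trait_noise_sd, len(design))
        if trait == config.colonization_trait:
            vals = np.clip(
                config.colonization_center + config.colonization_scale * lin, 0.0, 1.0
            )
            vals[(~inoculated_mask(design)).to_numpy()] = 0.0
        else:
            vals = lin
        out[trait] = vals
    return out


# ---------------------------------------------------------------------------
# top level


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimData:
    """Generate a complete synthetic dual dataset.

    All randomness flows from ``config.seed`` (overridden by ``seed``)
    through named substreams, so identical configs give byte-identical
    outputs.
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_factors, rng_counts, rng_traits = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    design_seed = int(rng_design.integers(0, 2**31 - 1))
    design = generate_design(
        config.n_cultivars,
        config.n_fungal_levels,
        config.n_reps,
        config.n_blocks,
        seed=design_seed,
    )
    factors, truth = generate_latent_factors(design, config, rng=rng_factors)
    host, sym, truth = generate_counts(design, factors, config, truth, rng=rng_counts)
    traits = generate_traits(design, factors, config, rng=rng_traits)
    return SimData(
        design=design,
        host_counts=host,
        sym_counts=sym,
        traits=traits,
        factors=factors,
        truth=truth,
        config=config,
    )


def write_dataset(data: SimData, outdir) -> dict[str, str]:
    """Write the simulated bundle as TSV + JSON files; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write_counts(cm: CountMatrix, name: str) -> None:
        df = cm.counts.copy()
        df.insert(0, "gene_id", df.index)
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)

    _write_counts(data.host_counts, "host_counts.tsv")
    _write_counts(data.sym_counts, "fungus_counts.tsv")

    meta = data.design[
        ["sample_id", "cultivar", "fungal_treatment", "block", "replicate"]
    ]
    p = outdir / "metadata.tsv"
    meta.to_csv(p, sep="\t", index=False)
    paths["metadata.tsv"] = str(p)

    traits = data.traits.copy()
    traits.insert(0, "sample_id", traits.index)
    p = outdir / "traits.tsv"
    traits.to_csv(p, sep="\t", index=False)
    paths["traits.tsv"] = str(p)

    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(data.truth.to_dict(), fh, indent=1, sort_keys=True)
    paths["truth.json"] = str(p)
    return paths
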