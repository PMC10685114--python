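"""Synthetic cohort generator with ground truth.

Generates longitudinal vaginal-microbiota-like cohorts with the statistical
structure the downstream analyses assume: per-participant mixed topic
memberships with logistic-normal AR(1) temporal autocorrelation, near
point-mass *Lactobacillus* topics plus diverse anaerobe topics, one topic
holding four mutually exclusive "synonym" genera (participant-level
exclusion), multinomial sequencing with log-normal library sizes, semi-Markov
bleeding diaries, menses-coupled shifts in topic proportions, and cyclic
metabolite/cytokine signals with LOQ censoring and missingness.

Every array is reproduced bit-identically for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import AssayMatrix, CYCLE_PERIOD
from .data_model import CompositionMatrix, CountMatrix, DataError

# ---------------------------------------------------------------------------
# Default taxa catalogue and topic templates

LACTOBACILLUS_TAXA = (
    "Lactobacillus_crispatus",
    "Lactobacillus_iners",
    "Lactobacillus_gasseri",
    "Lactobacillus_jensenii",
)

SYNONYM_GENERA = (
    "Streptococcus_agalactiae",
    "Enterococcus_faecalis",
    "Bifidobacterium_breve",
    "Staphylococcus_epidermidis",
)

ANAEROBE_TAXA = (
    "Gardnerella_vaginalis_G1",
    "Gardnerella_vaginalis_G2",
    "Gardnerella_vaginalis_G3",
    "Atopobium_vaginae",
    "Megasphaera_lornae",
    "Lachnocurva_vaginae",
    "Sneathia_amnii",
    "Sneathia_sanguinegens",
    "Prevotella_bivia",
    "Prevotella_amnii",
    "Prevotella_timonensis",
    "Mobiluncus_mulieris",
    "Dialister_micraerophilus",
    "Aerococcus_christensenii",
)

IVC_BACKGROUND_TAXA = (
    "Corynebacterium_sp",
    "Finegoldia_magna",
    "Peptoniphilus_sp",
    "Anaerococcus_tetradius",
    "Prevotella_disiens",
)

OTHER_TAXA = (
    "Ureaplasma_parvum",
    "Mycoplasma_hominis",
    "Veillonella_montpellierensis",
    "Fusobacterium_nucleatum",
    "Porphyromonas_uenonis",
    "Campylobacter_ureolyticus",
    "Actinomyces_neuii",
    "Fannyhessea_sp",
    "Clostridiales_BVAB2",
    "Parvimonas_micra",
    "Gemella_haemolysans",
    "Escherichia_coli",
    "Atopobium_sp",
)

DEFAULT_TAXA = LACTOBACILLUS_TAXA + SYNONYM_GENERA + ANAEROBE_TAXA + IVC_BACKGROUND_TAXA + OTHER_TAXA


def _point_mass(taxa: tuple[str, ...], taxon: str, mass: float = 0.95) -> dict[str, float]:
    rest = (1.0 - mass) / (len(taxa) - 1)
    return {t: (mass if t == taxon else rest) for t in taxa}


def _default_templates(taxa: tuple[str, ...]) -> dict[str, dict[str, float]]:
    anaerobe = {
        "Gardnerella_vaginalis_G1": 0.22, "Gardnerella_vaginalis_G2": 0.12,
        "Gardnerella_vaginalis_G3": 0.06, "Atopobium_vaginae": 0.16,
        "Megasphaera_lornae": 0.12, "Lachnocurva_vaginae": 0.08,
        "Sneathia_amnii": 0.06, "Prevotella_bivia": 0.05, "Prevotella_amnii": 0.04,
        "Mobiluncus_mulieris": 0.03, "Dialister_micraerophilus": 0.02,
        "Aerococcus_christensenii": 0.02,
    }
    spread = (1.0 - sum(anaerobe.values())) / (len(taxa) - len(anaerobe))
    anaerobe_full = {t: anaerobe.get(t, spread) for t in taxa}
    ivc_background = {
        "Corynebacterium_sp": 0.12, "Finegoldia_magna": 0.10,
        "Peptoniphilus_sp": 0.08, "Anaerococcus_tetradius": 0.05,
        "Prevotella_disiens": 0.05,
    }
    return {
        "I": _point_mass(taxa, "Lactobacillus_crispatus", 0.95),
        "II": _point_mass(taxa, "Lactobacillus_gasseri", 0.93),
        "III": _point_mass(taxa, "Lactobacillus_iners", 0.95),
        "V": _point_mass(taxa, "Lactobacillus_jensenii", 0.93),
        "IV-B": anaerobe_full,
        "IV-C": ivc_background,  # synonym genera filled in by make_reference_topics
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``templates`` maps topic name → taxon → proportion.  The topic named
    ``synonym_topic`` receives equal mass (1 − background)/4 on the four
    ``synonym_genera`` in addition to its stated background composition.
    """

    n_participants: int = 20
    samples_per_participant: int = 15
    # daily-sampling span for non-pregnant participants (the study design has
    # ~70 daily samples non-pregnant vs weekly samples in pregnancy); None
    # falls back to samples_per_participant
    nonpregnant_days: int | None = None
    taxa: tuple[str, ...] = DEFAULT_TAXA
    templates: dict[str, dict[str, float]] = field(default_factory=lambda: _default_templates(DEFAULT_TAXA))
    synonym_topic: str = "IV-C"
    synonym_genera: tuple[str, ...] = SYNONYM_GENERA
    menses_topics: tuple[str, ...] = ("IV-C",)
    baseline_concentration: float = 0.25  # symmetric Dirichlet mass per topic
    anchor_boost: float = 8.0  # extra concentration on one participant-specific topic
    anchor_topics: tuple[str, ...] | None = None  # rotation set; None = all topics
    # baseline (non-anchored) expression of the synonym topic is damped: these
    # sub-communities are episodic/menses-associated rather than a persistent
    # part of most participants' baseline community
    synonym_baseline_damping: float = 0.1
    rho: float = 0.7  # AR(1) coefficient of logit-scale noise
    sigma: float = 0.5  # stationary sd of logit-scale noise
    menses_effect: float = 3.0  # additive log-odds shift toward menses topics
    library_mu: float = float(np.log(20_000))
    library_sigma: float = 0.5
    fraction_pregnant: float = 0.5
    # semi-Markov bleeding-diary process
    mean_cycle_length: float = 28.0
    cycle_sd: float = 3.0
    menses_length: float = 4.0
    menses_sd: float = 1.0
    spotting_rate: float = 0.05
    initial_phase: int | None = None  # days since last onset at day 0; random if None
    # assay simulation
    assay_n_features: int = 30
    assay_fraction_cyclic: float = 0.4
    assay_amplitude: float = 1.0  # in units of the noise sd
    assay_lloq_quantile: float = 0.1
    assay_uloq_quantile: float = 0.95
    assay_missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise DataError("rho must lie in [0, 1)")
        if self.K_true < 2:
            raise DataError("need at least 2 topic templates")
        if self.assay_amplitude < 0:
            raise DataError("assay amplitude must be ≥ 0")
        for p in (self.fraction_pregnant, self.spotting_rate, self.assay_fraction_cyclic,
                  self.assay_missing_rate, self.assay_lloq_quantile, self.assay_uloq_quantile):
            if not 0 <= p <= 1:
                raise DataError("probabilities must lie in [0, 1]")

    @property
    def K_true(self) -> int:
        return len(self.templates)

    @property
    def topic_names(self) -> list[str]:
        return list(self.templates)


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    meta: pd.DataFrame  # SampleTable
    true_beta: CompositionMatrix  # template topics (synonym topic with all 4 genera)
    effective_beta: CompositionMatrix  # usage-weighted realized topics (participant-level
    # synonym exclusion makes these differ from the template in the synonym topic)
    true_gamma: pd.DataFrame  # samples × topics
    true_cycle_onsets: dict[str, list[int]]
    true_menses_days: dict[str, set[int]]
    synonym_choice: dict[str, str]  # participant → retained synonym genus
    metabolites: AssayMatrix | None = None
    cytokines: AssayMatrix | None = None
    assay_truth: pd.DataFrame | None = None  # feature, cyclic flag, peak day


def make_reference_topics(config: GeneratorConfig) -> CompositionMatrix:
    """Build the K_true × V row-stochastic topic matrix from the templates.

    The synonym topic gets equal mass on the four synonym genera on top of its
    shared background; all other templates are used as stated.
    """
    V = len(config.taxa)
    tidx = {t: i for i, t in enumerate(config.taxa)}
    beta = np.zeros((config.K_true, V))
    for k, (name, template) in enumerate(config.templates.items()):
        unknown = set(template) - set(config.taxa)
        if unknown:
            raise DataError(f"template {name!r} uses unknown taxa {sorted(unknown)}")
        for t, v in template.items():
            beta[k, tidx[t]] = v
        if name == config.synonym_topic:
            background = beta[k].sum()
            share = (1.0 - background) / len(config.synonym_genera)
            for g in config.synonym_genera:
                beta[k, tidx[g]] = share
        if not np.isclose(beta[k].sum(), 1.0, atol=1e-8):
            raise DataError(f"template {name!r} sums to {beta[k].sum():.6f}, not 1")
    return CompositionMatrix(config.topic_names, list(config.taxa), beta)


def simulate_bleeding_diary(
    config: GeneratorConfig, n_days: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Semi-Markov bleeding diary: daily scores 0–3 plus true menses onsets.

    Menses segments have discretized-normal duration with scores 1–3 on every
    day; inter-menses segments last (cycle length − menses length) days with
    score 0, each day spotting (score 1) with probability ``spotting_rate``.
    Onsets within [0, n_days) are recorded.
    """
    if n_days < 1:
        raise DataError("n_days must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.zeros(n_days, dtype=int)
    onsets: list[int] = []

    def menses_len() -> int:
        return max(1, int(round(rng.normal(config.menses_length, config.menses_sd))))

    def cycle_len(mlen: int) -> int:
        c = int(round(rng.normal(config.mean_cycle_length, config.cycle_sd)))
        return max(mlen + 5, c)

    if config.initial_phase is None:
        phase = int(rng.integers(0, int(config.mean_cycle_length)))
    else:
        phase = int(config.initial_phase)
    day = -phase  # onset of the cycle containing day 0
    while day < n_days:
        mlen = menses_len()
        clen = cycle_len(mlen)
        if day >= 0:
            onsets.append(day)
        for d in range(day, min(day + mlen, n_days)):
            if d >= 0:
                scores[d] = rng.choice([1, 2, 3], p=[0.3, 0.45, 0.25])
        for d in range(day + mlen, min(day + clen, n_days)):
            if d >= 0 and rng.random() < config.spotting_rate:
                scores[d] = 1
        day += clen
    return scores, onsets


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Simulate the full longitudinal cohort with ground truth.

    Per participant: a baseline topic mixture from an anchored Dirichlet,
    logistic-normal AR(1) day-to-day drift of the topic logits, an additive
    ``menses_effect`` on the menses topics' logits during menses days
    (non-pregnant only), participant-level synonym exclusion (three of the
    four synonym genera zeroed in that participant's synonym-topic row), and
    multinomial counts at a log-normal library size.
    """
    rng = np.random.default_rng(config.seed)
    beta_template = make_reference_topics(config)
    K, V = config.K_true, len(config.taxa)
    tidx = {t: i for i, t in enumerate(config.taxa)}
    topic_names = config.topic_names
    menses_topic_idx = [topic_names.index(t) for t in config.menses_topics]
    syn_topic_idx = topic_names.index(config.synonym_topic) if config.synonym_topic in topic_names else None

    sample_ids: list[str] = []
    rows_meta: list[dict] = []
    counts_rows: list[np.ndarray] = []
    gamma_rows: list[np.ndarray] = []
    onsets_by_p: dict[str, list[int]] = {}
    menses_days_by_p: dict[str, set[int]] = {}
    synonym_choice: dict[str, str] = {}

    eff_beta_num = np.zeros((K, V))  # expected token allocation per topic × taxon
    for p in range(config.n_participants):
        pid = f"P{p + 1:03d}"
        pregnant = rng.random() < config.fraction_pregnant
        cohort = ("P-SU" if rng.random() < 0.3 else "P-UAB") if pregnant else "NP-UAB"
        race = rng.choice(["Black", "White", "Other"], p=[0.45, 0.40, 0.15])

        # anchors rotate over topics so every sub-community is represented,
        # mirroring a cohort selected to include each community type
        conc = np.full(K, config.baseline_concentration)
        if config.anchor_topics is None:
            anchor = p % K
        else:
            anchor = topic_names.index(config.anchor_topics[p % len(config.anchor_topics)])
        conc[anchor] += config.anchor_boost
        if syn_topic_idx is not None and anchor != syn_topic_idx:
            conc[syn_topic_idx] *= config.synonym_baseline_damping
        baseline = rng.dirichlet(conc)
        base_logit = np.log(baseline + 1e-8)

        beta_p = beta_template.values.copy()
        if syn_topic_idx is not None:
            # variant assignment decorrelated from the anchor rotation so each
            # anchor co-occurs with every synonym variant across the cohort
            n_var = len(config.synonym_genera)
            L = K if config.anchor_topics is None else len(config.anchor_topics)
            vi = p % n_var if np.gcd(L, n_var) == 1 else (p // L) % n_var
            keep = config.synonym_genera[vi]
            synonym_choice[pid] = keep
            # the kept genus takes over the whole synonym niche: the zeroed
            # genera's mass transfers to it, the background stays untouched
            niche = sum(beta_p[syn_topic_idx, tidx[g]] for g in config.synonym_genera)
            for g in config.synonym_genera:
                beta_p[syn_topic_idx, tidx[g]] = niche if g == keep else 0.0
            beta_p[syn_topic_idx] /= beta_p[syn_topic_idx].sum()

        if pregnant:
            n_t = config.samples_per_participant
            days = 7 * np.arange(n_t)
            menses_days: set[int] = set()
            onsets: list[int] = []
            diary = None
        else:
            n_t = config.nonpregnant_days or config.samples_per_participant
            days = np.arange(n_t)
            diary, onsets = simulate_bleeding_diary(config, n_t, rng)
            # menses = the contiguous bleeding run starting at each onset
            menses_days = set()
            for onset in onsets:
                d = onset
                while d < n_t and diary[d] >= 1:
                    menses_days.add(d)
                    d += 1
        onsets_by_p[pid] = onsets
        menses_days_by_p[pid] = menses_days

        eps = rng.normal(0.0, config.sigma, size=K)
        innov_sd = config.sigma * np.sqrt(1.0 - config.rho**2)
        preterm_risk_gammas = []
        for t in range(n_t):
            if t > 0:
                eps = config.rho * eps + rng.normal(0.0, innov_sd, size=K)
            logits = base_logit + eps
            if (not pregnant) and int(days[t]) in menses_days:
                for k in menses_topic_idx:
                    logits[k] += config.menses_effect
            g = np.exp(logits - logits.max())
            g /= g.sum()
            gamma_rows.append(g)
            preterm_risk_gammas.append(g)
            lib = int(np.clip(rng.lognormal(config.library_mu, config.library_sigma), 500, 2e6))
            probs = g @ beta_p
            counts_rows.append(rng.multinomial(lib, probs / probs.sum()))
            eff_beta_num += (lib * g)[:, None] * beta_p
            lacto = sum(probs[tidx[t_]] for t_ in LACTOBACILLUS_TAXA if t_ in tidx)
            ph = float(np.clip(4.2 + 1.2 * (1 - lacto)
                               + (0.4 if (not pregnant) and int(days[t]) in menses_days else 0.0)
                               + rng.normal(0, 0.15), 3.5, 8.0))
            rows_meta.append(
                {
                    "sample": f"{pid}_d{int(days[t]):03d}",
                    "participant": pid,
                    "cohort": cohort,
                    "pregnant": pregnant,
                    "race": race,
                    "day": int(days[t]),
                    "preterm": np.nan,
                    "ph": ph if not pregnant else np.nan,
                    "bleeding": int(diary[t]) if diary is not None else np.nan,
                }
            )
            sample_ids.append(f"{pid}_d{int(days[t]):03d}")
        if pregnant and syn_topic_idx is not None:
            mean_risk = float(np.mean([g[syn_topic_idx] for g in preterm_risk_gammas]))
            p_pre = 1.0 / (1.0 + np.exp(-(-1.5 + 2.5 * mean_risk)))
            preterm = bool(rng.random() < p_pre)
            for r in rows_meta[-n_t:]:
                r["preterm"] = preterm

    meta = pd.DataFrame(rows_meta).set_index("sample")
    counts = np.vstack(counts_rows)
    gamma_true = np.vstack(gamma_rows)
    cm = CountMatrix(sample_ids=sample_ids, taxon_ids=list(config.taxa), counts=counts)
    eff = eff_beta_num / eff_beta_num.sum(axis=1, keepdims=True)
    cohort = SyntheticCohort(
        counts=cm,
        meta=meta,
        true_beta=beta_template,
        effective_beta=CompositionMatrix(topic_names, list(config.taxa), eff),
        true_gamma=pd.DataFrame(gamma_true, index=sample_ids, columns=topic_names),
        true_cycle_onsets=onsets_by_p,
        true_menses_days=menses_days_by_p,
        synonym_choice=synonym_choice,
    )
    return cohort


def simulate_assays(
    config: GeneratorConfig, cycledays: np.ndarray, seed: int | np.random.Generator
) -> tuple[AssayMatrix, pd.DataFrame]:
    """Simulate assay features over standardized cycledays (−18…+7).

    Cyclic features have mean amplitude·cos(2π(d − peak)/26) on the
    transformed scale with unit-sd Gaussian noise; values are censored at the
    configured LLOQ/ULOQ quantiles and missing completely at random.
    Returns the matrix plus the per-feature truth table (cyclic flag, peak).
    """
    cycledays = np.asarray(cycledays)
    if np.any(cycledays < -18) or np.any(cycledays > 7):
        raise DataError("cycledays must lie in [-18, +7]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = len(cycledays), config.assay_n_features
    cyclic = rng.random(m) < config.assay_fraction_cyclic
    peaks = rng.integers(-18, 8, size=m)
    mean = np.zeros((n, m))
    for j in range(m):
        if cyclic[j]:
            mean[:, j] = config.assay_amplitude * np.cos(
                2 * np.pi * (cycledays - peaks[j]) / CYCLE_PERIOD
            )
    values = mean + rng.normal(0.0, 1.0, size=(n, m))
    lloq = np.quantile(values, config.assay_lloq_quantile, axis=0)
    uloq = np.quantile(values, config.assay_uloq_quantile, axis=0)
    values = np.clip(values, lloq[None, :], uloq[None, :])
    miss = rng.random((n, m)) < config.assay_missing_rate
    values = np.where(miss, np.nan, values)
    features = [f"F{j + 1:03d}" for j in range(m)]
    assay = AssayMatrix(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        feature_ids=features,
        values=values,
        lloq=lloq,
        uloq=uloq,
        transform="raw",
    )
    truth = pd.DataFrame({"feature": features, "cyclic": cyclic, "peak_day": peaks})
    return assay, truth


def default_centroids():
    """Reference sub-CST centroid set over the default taxa catalogue.

    Thirteen centroids mimicking the published sub-CST structure: fully vs
    partially *Lactobacillus*-dominated pairs (I-A/I-B, III-A/III-B), single
    II and V, two anaerobe centroids (IV-A, IV-B), and the IV-C0…IV-C4 series
    in which four mutually exclusive genera each dominate one centroid.
    Synthetic stand-in for the published centroid table (user-supplied in real
    analyses); identity harmonization.
    """
    from .reference import ReferenceCentroids

    taxa = DEFAULT_TAXA
    tidx = {t: i for i, t in enumerate(taxa)}

    def comp(spec: dict[str, float]) -> np.ndarray:
        row = np.zeros(len(taxa))
        for t, v in spec.items():
            row[tidx[t]] = v
        rest = 1.0 - row.sum()
        others = row == 0
        row[others] = rest / others.sum()
        return row

    ivc_bg = {
        "Corynebacterium_sp": 0.12, "Finegoldia_magna": 0.10,
        "Peptoniphilus_sp": 0.07, "Anaerococcus_tetradius": 0.05,
        "Prevotella_disiens": 0.04,
    }
    defs = {
        "I-A": {"Lactobacillus_crispatus": 0.97},
        "I-B": {"Lactobacillus_crispatus": 0.62, "Lactobacillus_iners": 0.14,
                "Gardnerella_vaginalis_G1": 0.08, "Atopobium_vaginae": 0.05},
        "II": {"Lactobacillus_gasseri": 0.92},
        "III-A": {"Lactobacillus_iners": 0.96},
        "III-B": {"Lactobacillus_iners": 0.60, "Gardnerella_vaginalis_G1": 0.12,
                  "Atopobium_vaginae": 0.10, "Megasphaera_lornae": 0.06},
        "IV-A": {"Lachnocurva_vaginae": 0.24, "Gardnerella_vaginalis_G1": 0.16,
                 "Atopobium_vaginae": 0.10, "Megasphaera_lornae": 0.11,
                 "Sneathia_amnii": 0.08, "Prevotella_bivia": 0.07,
                 "Prevotella_amnii": 0.05},
        "IV-B": {"Gardnerella_vaginalis_G1": 0.30, "Gardnerella_vaginalis_G2": 0.15,
                 "Atopobium_vaginae": 0.19, "Megasphaera_lornae": 0.08,
                 "Sneathia_amnii": 0.05, "Prevotella_bivia": 0.05},
        "IV-C0": dict(ivc_bg, **{g: 0.08 for g in SYNONYM_GENERA}),
        "IV-C1": dict(ivc_bg, Streptococcus_agalactiae=0.52),
        "IV-C2": dict(ivc_bg, Enterococcus_faecalis=0.52),
        "IV-C3": dict(ivc_bg, Bifidobacterium_breve=0.52),
        "IV-C4": dict(ivc_bg, Staphylococcus_epidermidis=0.52),
        "V": {"Lactobacillus_jensenii": 0.93},
    }
    values = np.vstack([comp(s) for s in defs.values()])
    return ReferenceCentroids(
        labels=list(defs), taxon_ids=list(taxa), values=values, harmonization={}
    )


# ---------------------------------------------------------------------------
# Dominance-loss transition generator


def simulate_transition_cohort(
    n_participants: int = 100,
    pairs_per_participant: int = 30,
    hazard_intercept: float = -4.5,
    hazard_weights: dict[str, float] | None = None,
    library_size: int = 20_000,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Consecutive-sample pairs whose dominance-loss hazard is logit-linear in γ.

    Each participant anchors on a *Lactobacillus* topic; per pair, the current
    mixture γ is drawn around that anchor, the probability that the next
    sample loses *Lactobacillus* dominance is sigmoid(intercept + w·γ), and
    the next composition is drawn accordingly.  Returns one row per pair with
    participant, true γ features, current counts, current/next *Lactobacillus*
    totals.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    beta = make_reference_topics(config).values
    names = config.topic_names
    tidx = {t: i for i, t in enumerate(config.taxa)}
    lacto_cols = [tidx[t] for t in LACTOBACILLUS_TAXA if t in tidx]
    if hazard_weights is None:
        hazard_weights = {"III": 5.0, "IV-B": 8.0, "IV-C": 8.0}
    w = np.array([hazard_weights.get(nm, 0.0) for nm in names])
    lacto_topics = [k for k, nm in enumerate(names) if nm in ("I", "II", "III", "V")]
    anaerobe_topics = [k for k, nm in enumerate(names) if nm not in ("I", "II", "III", "V")]

    rows = []
    for p in range(n_participants):
        pid = f"T{p + 1:03d}"
        anchor = lacto_topics[p % len(lacto_topics)]
        for t in range(pairs_per_participant):
            conc = np.full(len(names), 0.4)
            conc[anchor] += 6.0
            conc[anaerobe_topics] += rng.uniform(0, 1.2, size=len(anaerobe_topics))
            gam = rng.dirichlet(conc)
            comp = gam @ beta
            cnt = rng.multinomial(library_size, comp / comp.sum())
            cur_lacto = comp[lacto_cols].sum()
            p_loss = 1.0 / (1.0 + np.exp(-(hazard_intercept + w @ gam)))
            loss = bool(rng.random() < p_loss)
            if loss:
                conc2 = np.full(len(names), 0.3)
                conc2[anaerobe_topics] += 5.0
            else:
                conc2 = conc
            gam2 = rng.dirichlet(conc2)
            comp2 = gam2 @ beta
            rows.append(
                {
                    "participant": pid,
                    "pair": f"{pid}_t{t:02d}",
                    **{f"gamma_{nm}": gam[k] for k, nm in enumerate(names)},
                    "counts": cnt,
                    "current_lacto": float(cur_lacto),
                    "next_lacto": float(comp2[lacto_cols].sum()),
                }
            )
    return pd.DataFrame(rows)
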