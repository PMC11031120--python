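"""Seeded synthetic trial data with a planted outcome model.

Every component the predictor consumes — a disease ontology, molecules with
latent pharmacological attributes, templated eligibility criteria, auxiliary
ADMET tables and labeled trials — is generated from one integer seed.  The
planted model is linear-logistic in three interpretable drivers:

    latent = b_tox * (mean molecule toxicity - 1/2)
           + b_risk * (max disease risk - 1/2)
           + b_prot * protocol quality
           + phase offset

with Gaussian label noise on top; phase offsets are calibrated so the
marginal success rates match the observed clinical phase marginals
(56.3% / 49.8% / 67.8% for phases I/II/III).  Because each input tier
carries its own coefficient, ablation experiments can attribute predictive
signal to specific nodes of the interaction graph.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .hintnet.records import TrialRecord, Ontology, PHASES
from .riskcal import ScoredSample

__all__ = ["SynthConfig", "PlantedTruth", "SMILES_VOCAB", "gen_ontology",
           "gen_trials", "gen_admet_tables", "gen_disease_risk_table",
           "calibrate_bayes_noise", "make_scored_sampler"]

# Hand-validated small-molecule SMILES; sampled with replacement so trial
# generation never needs a chemistry toolkit.
SMILES_VOCAB = [
    "CCO", "CCCO", "CCCCO", "CC(C)O", "CC(C)CO",
    "CCN", "CCCN", "CC(C)N", "CCNCC", "CN(C)C",
    "CC(=O)O", "CCC(=O)O", "CC(=O)N", "CC(=O)NC", "CC(=O)OC",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "COc1ccccc1", "CC(=O)c1ccccc1", "c1ccncc1", "Cc1ccncc1", "c1ccoc1",
    "c1ccsc1", "c1cc[nH]c1", "Cn1ccnc1", "c1cnc2ccccc2c1", "c1ccc2ccccc2c1",
    "CC(=O)Oc1ccccc1C(=O)O", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "CC(N)Cc1ccccc1", "NCCc1ccc(O)c(O)c1",
    "OCCN1CCN(CC1)C", "O=C(O)CCc1ccccc1", "O=C(N)c1ccccc1",
    "Clc1ccccc1", "Clc1ccc(Cl)cc1", "Fc1ccccc1", "FC(F)(F)c1ccccc1",
    "Brc1ccccc1", "O=S(=O)(N)c1ccccc1", "CS(=O)(=O)c1ccccc1",
    "OC(=O)c1ccccc1O", "CCOC(=O)c1ccccc1", "CNC(=O)c1ccccc1",
    "OCC(O)CO", "CC(O)C(=O)O",
]

_GOOD_SENTENCES = [
    "adults aged {lo} to {hi} years with confirmed diagnosis by biopsy",
    "randomized double blind placebo controlled design with predefined endpoints",
    "documented disease stage with centrally adjudicated outcome assessment",
    "stable baseline medication for at least eight weeks before enrollment",
    "adequate hepatic and renal function confirmed by laboratory screening",
    "written informed consent and ability to comply with scheduled visits",
]
_POOR_SENTENCES = [
    "any adult volunteer willing to participate in the study",
    "open label single arm design without a comparator group",
    "diagnosis by self report without laboratory confirmation",
    "no washout period required for prior experimental therapy",
    "endpoints to be determined during the course of the trial",
    "participants enrolled at the discretion of the site investigator",
]


@dataclass
class SynthConfig:
    """Study conditions for the generator; defaults mirror the benchmark
    marginals (phase mix and per-phase success rates)."""

    n_trials: int = 1000
    phase_mix: tuple = (0.143, 0.490, 0.367)
    phase_success_rates: tuple = (0.563, 0.498, 0.678)
    ontology_depth: int = 3
    branching: int = 3
    n_molecules: int = 50
    effect_sizes: tuple = (-5.0, -5.0, 3.0)  # toxicity, disease risk, protocol
    noise_sd: float = 2.0
    bayes_auc_target: float = 0.85
    admet_flip_noise: float = 0.05
    window_start: _dt.date = _dt.date(2010, 1, 1)
    window_days: int = 2192  # six years
    split_date: _dt.date = _dt.date(2013, 8, 7)  # 60% through the window
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.phase_mix) - 1.0) > 1e-9:
            raise ValueError("phase_mix fractions must sum to 1")
        for r in self.phase_success_rates:
            if not 0.0 < r < 1.0:
                raise ValueError("phase success rates must lie in (0,1)")
        if self.n_molecules > len(SMILES_VOCAB):
            raise ValueError(
                f"n_molecules capped at {len(SMILES_VOCAB)} distinct structures")


@dataclass
class PlantedTruth:
    """Ground truth behind one generated dataset."""

    latent: np.ndarray            # per-trial latent score (incl. phase offset)
    bayes_prob: np.ndarray        # sigmoid(latent): best achievable scorer
    disease_risk: dict            # code -> planted failure risk in (0,1)
    molecule_toxicity: dict       # smiles -> planted toxicity in (0,1)
    molecule_attrs: dict = field(default_factory=dict)  # prop -> {smiles: value}
    protocol_quality: np.ndarray | None = None
    phase_offsets: dict = field(default_factory=dict)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def gen_ontology(depth: int, branching: int, seed: int = 0) -> Ontology:
    """Balanced single-root code tree, ICD-hierarchy-like."""
    if depth < 0 or branching < 1:
        raise ValueError("depth must be >= 0 and branching >= 1")
    edges = []
    frontier = ["R00"]
    for level in range(depth):
        nxt = []
        for parent in frontier:
            for b in range(branching):
                child = f"{parent}.{b}"
                edges.append((child, parent))
                nxt.append(child)
        frontier = nxt
    if not edges:
        return Ontology.single_root("R00")
    return Ontology(edges)


def _disease_risks(ontology: Ontology, rng: np.random.Generator) -> dict:
    """Risk diffuses down the hierarchy: children jitter around parents."""
    risks = {ontology.root: 0.5}
    order = [ontology.root]
    children: dict[str, list[str]] = {}
    for child, parent in ontology.parent_edges():
        children.setdefault(parent, []).append(child)
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for child in sorted(children.get(node, [])):
            risks[child] = float(np.clip(
                risks[node] + rng.normal(0.0, 0.16), 0.05, 0.95))
            order.append(child)
    return risks


def gen_trials(config: SynthConfig) -> tuple[list[TrialRecord], PlantedTruth]:
    """Labeled trials plus the planted truth that generated them."""
    rng = np.random.default_rng(config.seed)
    ontology = gen_ontology(config.ontology_depth, config.branching, config.seed)
    leaves = ontology.leaves()
    molecules = SMILES_VOCAB[:config.n_molecules]

    mol_attrs = {prop: {m: float(rng.uniform()) for m in molecules}
                 for prop in ("absorption", "distribution", "metabolism",
                              "excretion", "toxicity")}
    disease_risk = _disease_risks(ontology, rng)

    n = config.n_trials
    phases = rng.choice(len(PHASES), size=n, p=np.asarray(config.phase_mix))
    b_tox, b_risk, b_prot = config.effect_sizes

    trials_raw = []
    signal = np.zeros(n)
    quality = np.zeros(n)
    for i in range(n):
        drugs = [str(m) for m in
                 rng.choice(molecules, size=rng.integers(1, 4), replace=False)]
        diseases = [str(c) for c in
                    rng.choice(leaves, size=rng.integers(1, 3), replace=False)]
        # protocol quality is a property of the realized document: the
        # balance of rigorous vs sloppy criteria actually written down
        q_intent = float(rng.uniform(-1.0, 1.0))
        n_crit = int(rng.integers(2, 7))
        protocol = []
        n_good = 0
        for k in range(n_crit):
            good = rng.uniform() < (1.0 + q_intent) / 2.0
            n_good += int(good)
            pool = _GOOD_SENTENCES if good else _POOR_SENTENCES
            tmpl = pool[int(rng.integers(len(pool)))]
            lo = int(rng.integers(18, 45))
            sentence = tmpl.format(lo=lo, hi=lo + int(rng.integers(10, 40)))
            tag = "+" if k < max(1, n_crit // 2) else "-"
            protocol.append((tag, sentence))
        q = 2.0 * n_good / n_crit - 1.0
        quality[i] = q
        mean_tox = float(np.mean([mol_attrs["toxicity"][m] for m in drugs]))
        max_risk = float(max(disease_risk[c] for c in diseases))
        signal[i] = (b_tox * (mean_tox - 0.5) + b_risk * (max_risk - 0.5)
                     + b_prot * q)
        start = config.window_start + _dt.timedelta(
            days=int(rng.integers(0, config.window_days)))
        completion = start + _dt.timedelta(days=int(rng.integers(180, 1460)))
        trials_raw.append((drugs, diseases, protocol, start, completion))

    noise = rng.normal(0.0, config.noise_sd, size=n)
    # per-phase offsets solved so marginal success rates hit their targets
    offsets = {}
    for pi, phase in enumerate(PHASES):
        mask = phases == pi
        target = config.phase_success_rates[pi]
        if mask.sum() == 0:
            offsets[phase] = 0.0
            continue
        s = signal[mask] + noise[mask]
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _sigmoid(s + mid).mean() < target:
                lo = mid
            else:
                hi = mid
        offsets[phase] = 0.5 * (lo + hi)

    offset_arr = np.array([offsets[PHASES[p]] for p in phases])
    latent = signal + offset_arr
    bayes_prob = _sigmoid(latent)
    label_prob = _sigmoid(latent + noise)
    labels = (rng.uniform(size=n) < label_prob).astype(int)

    trials = []
    for i, (drugs, diseases, protocol, start, completion) in enumerate(trials_raw):
        trials.append(TrialRecord(
            trial_id=f"T{i:05d}", drugs=drugs, diseases=diseases,
            protocol=protocol, phase=PHASES[phases[i]],
            start_date=start, completion_date=completion,
            label=int(labels[i])))
    truth = PlantedTruth(latent=latent, bayes_prob=bayes_prob,
                         disease_risk=disease_risk,
                         molecule_toxicity=mol_attrs["toxicity"],
                         molecule_attrs=mol_attrs,
                         protocol_quality=quality,
                         phase_offsets=offsets)
    return trials, truth


def gen_admet_tables(config: SynthConfig, truth: PlantedTruth) -> dict:
    """Per-property (smiles, label) tables from thresholded planted attributes."""
    import pandas as pd

    rng = np.random.default_rng(config.seed + 10)
    tables = {}
    for prop, attrs in truth.molecule_attrs.items():
        rows = []
        for smiles, value in attrs.items():
            label = int(value > 0.5)
            if rng.uniform() < config.admet_flip_noise:
                label = 1 - label
            rows.append((smiles, label))
        tables[prop] = pd.DataFrame(rows, columns=["smiles", "label"])
    return tables


def gen_disease_risk_table(config: SynthConfig, truth: PlantedTruth,
                           rows_per_code: int = 20):
    """Historical per-disease outcomes: label ~ Bernoulli(1 - planted risk)."""
    import pandas as pd

    rng = np.random.default_rng(config.seed + 11)
    rows = []
    for code in sorted(truth.disease_risk):
        p_success = 1.0 - truth.disease_risk[code]
        for _ in range(rows_per_code):
            rows.append((code, int(rng.uniform() < p_success)))
    return pd.DataFrame(rows, columns=["code", "label"])


def calibrate_bayes_noise(config: SynthConfig, n: int = 5000,
                          tol: float = 0.005, max_iter: int = 30) -> SynthConfig:
    """Adjust noise_sd so the Bayes scorer's AUC matches bayes_auc_target.

    Label noise monotonically erodes the achievable AUC, so the routine
    bisects noise_sd against the AUC measured on a size-n draw.
    """
    from sklearn.metrics import roc_auc_score

    def auc_at(sd: float) -> float:
        probe = replace(config, n_trials=n, noise_sd=sd)
        trials, truth = gen_trials(probe)
        labels = np.array([t.label for t in trials])
        return roc_auc_score(labels, truth.bayes_prob)

    lo, hi = 0.01, 8.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = auc_at(mid)
        if abs(a - config.bayes_auc_target) < tol:
            return replace(config, noise_sd=mid)
        if a > config.bayes_auc_target:
            lo = mid
        else:
            hi = mid
    return replace(config, noise_sd=0.5 * (lo + hi))


def make_scored_sampler(miscalibration: float = 0.08,
                        conf_low: float = 0.5, conf_high: float = 1.0):
    """Sampler of i.i.d. scored predictions with confidence-dependent errors.

    Confidence is uniform on [conf_low, conf_high]; the chance of a correct
    prediction is the stated confidence minus a fixed overconfidence gap
    (`miscalibration`), emulating a model whose softmax overstates its
    reliability — the regime where a calibrated abstention threshold earns
    its keep.
    """

    def sampler(rng: np.random.Generator, n: int) -> list[ScoredSample]:
        conf = rng.uniform(conf_low, conf_high, size=n)
        p_correct = np.clip(conf - miscalibration, 0.0, 1.0)
        correct = rng.uniform(size=n) < p_correct
        true = (rng.uniform(size=n) < 0.5).astype(int)
        pred = np.where(correct, true, 1 - true)
        samples = []
        for c, p, t in zip(conf, pred, true):
            prob = c if p == 1 else 1.0 - c
            samples.append(ScoredSample.from_prob(float(prob), int(t)))
        return samples

    return sampler
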