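"""Synthetic drug libraries and directional DDI datasets with planted signal.

Real interaction datasets are licensed, so every pipeline stage is
exercised on generated data whose statistical structure matches what the
method assumes: valid SMILES, per-enzyme CYP roles with stated
probabilities, directional pair labels that are a (noisy) deterministic
function of the CYP interaction vector and two descriptor products, and
a long-tailed, geometrically decaying class-size distribution.

The decision table (single source of truth; tests reference these
constants):

* Let ``v`` be the signed CYP interaction vector of the ordered pair.
  If ``v`` is nonzero, the first nonzero enzyme ``e`` (panel order)
  decides the class: sign +1 (inhibition, increased victim exposure)
  gives class ``1 + (e mod 6)``; sign -1 (induction) gives
  ``7 + (e mod 6)``.
* If ``v`` is all zero the pair is CYP-silent and two descriptor
  products decide the class: ``u = MolLogP(victim) * MolWt(perp)`` and
  ``w = TPSA(victim) * MolMR(perp)`` — exactly the cross-product
  features named in ``RULE_CHEM_FEATURES``.  ``u`` above ``U_TAIL``
  gives class 19; otherwise class ``13 + 2*bin3(u) + bin2(w)`` with
  ``u`` binned at ``U_BINS`` and ``w`` split at ``W_SPLIT`` (classes
  13-18).
* With probability ``label_noise`` the label is replaced by a uniform
  draw over all ``n_classes`` (so the Bayes-optimal accuracy is exactly
  ``1 - noise * (k-1)/k``).
* Class sizes follow a geometric profile: classes are ranked by their
  natural frequency under the rule and target counts are multinomial
  with weights ``decay**rank``.

The fragment grammar (scaffold + two substituents) emits only valid
SMILES by construction; the substituent spellings differ between the
left and right attachment points to keep valences legal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_features import RDKitDescriptorProvider, cross_product_name, default_provider
from .cyp_features import CYP_PANEL, encode_perpetrator, encode_victim
from .data_io import DDIRecord, DrugRecord
from .errors import SimulationError
from .cyp_features import CYPProfile

# ---------------------------------------------------------------------------
# planted rule constants
# ---------------------------------------------------------------------------

#: Descriptor pairs (victim descriptor, perpetrator descriptor) the
#: CYP-silent rule reads; their cross-product feature names follow.
RULE_DESCRIPTOR_PAIRS: tuple[tuple[str, str], ...] = (
    ("MolLogP", "MolWt"),
    ("TPSA", "MolMR"),
)
RULE_CHEM_FEATURES: tuple[str, ...] = tuple(
    cross_product_name(a, b) for a, b in RULE_DESCRIPTOR_PAIRS
)

U_BINS: tuple[float, float] = (120.0, 320.0)
U_TAIL: float = 480.0
W_SPLIT: float = 1250.0

# ---------------------------------------------------------------------------
# fragment grammar
# ---------------------------------------------------------------------------

SCAFFOLDS: tuple[str, ...] = (
    "{a}c1ccc({b})cc1",   # benzene
    "{a}c1ccc({b})nc1",   # pyridine
    "{a}c1ccc({b})s1",    # thiophene
    "{a}c1ccc({b})o1",    # furan
    "{a}C1CCC({b})CC1",   # cyclohexane
    "{a}N1CCC({b})CC1",   # piperidine (N-attached)
    "{a}c1cnc({b})nc1",   # pyrimidine
    "{a}C1CCN({b})CC1",   # piperidine (C-attached)
)

# left-attachment fragments bond from their *last-written* heavy atom,
# so branched groups are spelled reversed relative to the right list
SUBSTITUENTS_LEFT: tuple[str, ...] = (
    "C", "CC", "CCC", "CCO", "OC", "N", "NC", "C(=O)O", "C(=O)OC",
    "Cl", "F", "Br", "FC(F)(F)", "S(=O)(=O)N", "CCN(C)C", "OCC",
    "N#C", "CO", "CN(C)C", "CCOC",
)
SUBSTITUENTS_RIGHT: tuple[str, ...] = (
    "C", "CC", "CCC", "CCO", "OC", "N", "NC", "C(=O)O", "C(=O)OC",
    "Cl", "F", "Br", "C(F)(F)F", "S(=O)(=O)N", "CCN(C)C", "OCC",
    "C#N", "CO", "CN(C)C", "CCOC",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Role probabilities are per enzyme and independent across enzymes;
    inhibitor and inducer are mutually exclusive on one enzyme by
    construction, so generated profiles never carry a role conflict.
    """

    n_drugs: int = 250
    n_pairs: int = 5000
    substrate_prob: float = 0.35
    inhibitor_prob: float = 0.12
    inducer_prob: float = 0.08
    label_noise: float = 0.05
    n_classes: int = 19
    class_decay: float = 0.75
    seed: int = 0
    #: enzymes the CYP side of the rule reads (None = full panel)
    rule_enzymes: tuple[str, ...] | None = None
    #: whether CYP-silent pairs are sub-classified by the chemical rule
    #: (False collapses them all into class 13)
    chem_rule: bool = True
    #: candidate pool size as a multiple of n_pairs
    candidate_multiplier: int = 8

    def __post_init__(self):
        for p in (self.substrate_prob, self.inhibitor_prob, self.inducer_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.inhibitor_prob + self.inducer_prob > 1.0:
            raise ValueError("inhibitor_prob + inducer_prob must be <= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")


def generate_drug_library(config: SimulationConfig) -> list[DrugRecord]:
    """Sample ``n_drugs`` drugs: grammar SMILES plus independent CYP profiles."""
    if config.n_drugs < 2:
        raise SimulationError("need at least 2 drugs")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    drugs = []
    for i in range(config.n_drugs):
        scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        a = SUBSTITUENTS_LEFT[rng.integers(len(SUBSTITUENTS_LEFT))]
        b = SUBSTITUENTS_RIGHT[rng.integers(len(SUBSTITUENTS_RIGHT))]
        smiles = scaffold.format(a=a, b=b)
        substrates, inhibitors, inducers = set(), set(), set()
        for enzyme in CYP_PANEL:
            if rng.random() < config.substrate_prob:
                substrates.add(enzyme)
            r = rng.random()
            if r < config.inhibitor_prob:
                inhibitors.add(enzyme)
            elif r < config.inhibitor_prob + config.inducer_prob:
                inducers.add(enzyme)
        profile = CYPProfile(f"D{i:04d}", frozenset(substrates),
                             frozenset(inhibitors), frozenset(inducers))
        drugs.append(DrugRecord(f"D{i:04d}", smiles, profile))
    return drugs


def _rule_descriptor_values(drugs, provider):
    """Per-drug values of the four descriptors the chemical rule reads."""
    names = provider.names
    idx = {n: names.index(n) for pair in RULE_DESCRIPTOR_PAIRS for n in pair}
    vals = {n: np.empty(len(drugs)) for n in idx}
    for k, d in enumerate(drugs):
        vec = provider.compute(d.smiles)
        for n, i in idx.items():
            vals[n][k] = vec[i]
    return vals


def _silent_class(u: float, w: float) -> int:
    if u > U_TAIL:
        return 19
    bin3 = 0 if u <= U_BINS[0] else (1 if u <= U_BINS[1] else 2)
    bin2 = 0 if w <= W_SPLIT else 1
    return 13 + 2 * bin3 + bin2


def rule_label(victim: DrugRecord, perpetrator: DrugRecord,
               config: SimulationConfig,
               provider: RDKitDescriptorProvider | None = None) -> int:
    """Noise-free label the decision table assigns to one ordered pair."""
    provider = provider or default_provider()
    v = encode_victim(victim.cyp_profile) * encode_perpetrator(perpetrator.cyp_profile)
    enzymes = config.rule_enzymes or CYP_PANEL
    for e in CYP_PANEL:
        if e not in enzymes:
            continue
        i = CYP_PANEL.index(e)
        if v[i] != 0:
            return (1 if v[i] > 0 else 7) + (i % 6)
    if not config.chem_rule:
        return 13
    vec_a = provider.compute(victim.smiles)
    vec_b = provider.compute(perpetrator.smiles)
    names = provider.names
    u = vec_a[names.index("MolLogP")] * vec_b[names.index("MolWt")]
    w = vec_a[names.index("TPSA")] * vec_b[names.index("MolMR")]
    return _silent_class(u, w)


def generate_ddi_dataset(
    drugs: list[DrugRecord],
    config: SimulationConfig,
    provider: RDKitDescriptorProvider | None = None,
) -> list[DDIRecord]:
    """Sample ``n_pairs`` labelled ordered pairs from the drug library.

    A candidate pool of ordered pairs is drawn, each candidate gets its
    rule label, and the dataset is composed so empirical class sizes
    follow the geometric imbalance profile (classes ranked by natural
    frequency, multinomial targets with weights ``decay**rank``).  If a
    class runs out of candidates the deficit is redistributed and
    logged.  Finally labels are perturbed by the uniform noise model.
    """
    provider = provider or default_provider()
    n = len(drugs)
    if n < 2:
        raise SimulationError("drug library must hold at least 2 drugs")
    n_total = n * (n - 1)
    if config.n_pairs > n_total:
        raise SimulationError(
            f"requested {config.n_pairs} pairs but only {n_total} ordered "
            f"pairs exist for {n} drugs")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    pool_size = min(n_total, max(config.n_pairs, config.candidate_multiplier * config.n_pairs))
    flat = rng.choice(n_total, size=pool_size, replace=False)
    ii = flat // (n - 1)
    jj = flat % (n - 1)
    jj = np.where(jj >= ii, jj + 1, jj)  # skip the diagonal

    V = np.array([encode_victim(d.cyp_profile) for d in drugs])
    P = np.array([encode_perpetrator(d.cyp_profile) for d in drugs])
    inter = V[ii] * P[jj]  # pool x 12
    if config.rule_enzymes is not None:
        mask = np.array([e in config.rule_enzymes for e in CYP_PANEL])
        inter = inter * mask

    labels = np.empty(pool_size, dtype=int)
    nonzero = inter != 0
    has_cyp = nonzero.any(axis=1)
    first = np.argmax(nonzero, axis=1)
    sign = inter[np.arange(pool_size), first]
    labels[has_cyp] = np.where(sign[has_cyp] > 0, 1, 7) + first[has_cyp] % 6

    silent = ~has_cyp
    if config.chem_rule:
        vals = _rule_descriptor_values(drugs, provider)
        u = vals["MolLogP"][ii[silent]] * vals["MolWt"][jj[silent]]
        w = vals["TPSA"][ii[silent]] * vals["MolMR"][jj[silent]]
        silent_labels = np.where(
            u > U_TAIL, 19,
            13 + 2 * np.digitize(u, U_BINS) + (w > W_SPLIT).astype(int))
        labels[silent] = silent_labels
    else:
        labels[silent] = 13

    # compose the geometric class-size profile
    observed = np.unique(labels)
    bucket = {c: rng.permutation(np.flatnonzero(labels == c)) for c in observed}
    ranked = sorted(observed, key=lambda c: (-len(bucket[c]), c))
    weights = np.array([config.class_decay ** r for r in range(len(ranked))])
    weights /= weights.sum()
    targets = rng.multinomial(config.n_pairs, weights)

    take = {c: min(int(t), len(bucket[c])) for c, t in zip(ranked, targets)}
    deficit = config.n_pairs - sum(take.values())
    for c in ranked:  # redistribute any shortfall to classes with spare candidates
        if deficit <= 0:
            break
        spare = len(bucket[c]) - take[c]
        extra = min(spare, deficit)
        take[c] += extra
        deficit -= extra
    if deficit > 0:
        raise SimulationError(
            f"candidate pool too small to realise {config.n_pairs} pairs")

    chosen = np.concatenate([bucket[c][: take[c]] for c in ranked])
    chosen = chosen[rng.permutation(len(chosen))]
    final_labels = labels[chosen]

    flip = rng.random(len(chosen)) < config.label_noise
    noise_labels = rng.integers(1, config.n_classes + 1, size=len(chosen))
    final_labels = np.where(flip, noise_labels, final_labels)

    return [
        DDIRecord(drugs[ii[c]].drug_id, drugs[jj[c]].drug_id, int(l))
        for c, l in zip(chosen, final_labels)
    ]


def bayes_accuracy(config: SimulationConfig) -> float:
    """Best achievable accuracy on generated data (uniform noise model)."""
    k = config.n_classes
    return 1.0 - config.label_noise * (k - 1) / k
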