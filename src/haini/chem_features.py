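"""Molecular descriptor vectors and pairwise interaction-feature operators.

Each drug is reduced to a fixed, ordered vector of ``p`` molecular
descriptors computed from its SMILES string (default ``p = 60``).  An
ordered drug pair (victim A, perpetrator B) is then turned into a single
feature row with one of three combination operators:

``cross_product``
    every product ``Fa(i) * Fb(j)`` laid out row-major with the victim
    index outer, giving ``p**2`` features (3600 with the default set);
``concat``
    the two vectors side by side, ``2p`` features;
``sum_product``
    all elementwise sums followed by all elementwise products, ``2p``
    features.

The cross product is the default operator throughout the pipeline because
it is the richest of the three and is the one the downstream consensus
selection is designed to prune.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import DimensionError, SmilesParseError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

# Fixed 60-descriptor panel: constitutional counts, topological/shape
# indices, and physico-chemical surface terms including the ten molar
# refractivity VSA bins (MRVSA1..MRVSA10 map to RDKit's SMR_VSA bins).
# Order is load-bearing: cross-product feature names and the planted
# simulation rule both reference positions in this list.
_RDKIT_NAME_MAP = {f"MRVSA{i}": f"SMR_VSA{i}" for i in range(1, 11)}

DEFAULT_DESCRIPTOR_NAMES: tuple[str, ...] = (
    # constitutional / counts
    "MolWt", "HeavyAtomMolWt", "HeavyAtomCount", "NumHAcceptors",
    "NumHDonors", "NumRotatableBonds", "NumHeteroatoms",
    "NumAromaticRings", "NumSaturatedRings", "NumAliphaticRings",
    "RingCount", "NHOHCount", "NOCount", "FractionCSP3",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    # topological / shape
    "Chi0", "Chi1", "Chi0n", "Chi1n", "Chi2n", "Chi3n", "Chi4n",
    "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
    "Kappa1", "Kappa2", "Kappa3", "HallKierAlpha", "BalabanJ",
    "BertzCT", "LabuteASA", "TPSA",
    # physico-chemical and VSA surface bins
    "MolLogP", "MolMR",
    "MRVSA1", "MRVSA2", "MRVSA3", "MRVSA4", "MRVSA5",
    "MRVSA6", "MRVSA7", "MRVSA8", "MRVSA9", "MRVSA10",
    "SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4",
    "SlogP_VSA5", "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8",
)

assert len(DEFAULT_DESCRIPTOR_NAMES) == 60


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered descriptor vector for a single drug."""

    drug_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise DimensionError(
                f"{self.drug_id}: {len(self.names)} names vs {len(self.values)} values"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class InteractionFeatureVector:
    """Pair-level feature row produced by one combination operator."""

    pair_id: str
    mode: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise DimensionError(
                f"{self.pair_id}: {len(self.names)} names vs {len(self.values)} values"
            )

    def __len__(self) -> int:
        return len(self.values)


class RDKitDescriptorProvider:
    """Computes the fixed descriptor panel with RDKit.

    Results are cached per canonical SMILES, so respellings of the same
    molecule hit the cache and are guaranteed identical.  Descriptors
    that come back NaN/inf are imputed to 0 with a logged warning, which
    keeps every downstream matrix dense and finite.
    """

    def __init__(self, descriptor_names: Sequence[str] = DEFAULT_DESCRIPTOR_NAMES):
        self.names: tuple[str, ...] = tuple(descriptor_names)
        self._funcs: list[Callable] = [
            getattr(Descriptors, _RDKIT_NAME_MAP.get(n, n)) for n in self.names
        ]
        self._cache: dict[str, np.ndarray] = {}

    def canonicalize(self, smiles: str) -> str:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(smiles)
        return Chem.MolToSmiles(mol)

    def compute(self, smiles: str) -> np.ndarray:
        canonical = self.canonicalize(smiles)
        cached = self._cache.get(canonical)
        if cached is not None:
            return cached.copy()
        mol = Chem.MolFromSmiles(canonical)
        values = np.empty(len(self._funcs))
        for i, func in enumerate(self._funcs):
            try:
                v = float(func(mol))
            except (ValueError, ZeroDivisionError, OverflowError):
                v = math.nan
            values[i] = v
        bad = ~np.isfinite(values)
        if bad.any():
            names = [self.names[i] for i in np.flatnonzero(bad)]
            logger.warning("imputing %s to 0 for %s", names, canonical)
            values[bad] = 0.0
        self._cache[canonical] = values
        return values.copy()


_default_provider: RDKitDescriptorProvider | None = None


def default_provider() -> RDKitDescriptorProvider:
    """Process-wide provider instance sharing one descriptor cache."""
    global _default_provider
    if _default_provider is None:
        _default_provider = RDKitDescriptorProvider()
    return _default_provider


def compute_descriptors(
    smiles: str,
    drug_id: str = "",
    provider: RDKitDescriptorProvider | None = None,
) -> DescriptorVector:
    """Descriptor vector for one molecule, canonicalized before caching.

    Raises
    ------
    SmilesParseError
        if the SMILES does not parse.
    """
    provider = provider or default_provider()
    return DescriptorVector(drug_id=drug_id, names=provider.names,
                            values=provider.compute(smiles))


def _check_aligned(fa: DescriptorVector, fb: DescriptorVector) -> None:
    if len(fa) != len(fb):
        raise DimensionError(f"length mismatch: {len(fa)} vs {len(fb)}")
    if fa.names != fb.names:
        raise DimensionError("descriptor name order differs between drugs")


def cross_product_name(name_i: str, name_j: str) -> str:
    """Name of the cross-product feature (victim descriptor first)."""
    return f"A:{name_i}*B:{name_j}"


def cross_product_features(
    fa: DescriptorVector, fb: DescriptorVector, pair_id: str = ""
) -> InteractionFeatureVector:
    """All pairwise products ``fa[i] * fb[j]``, victim index outer.

    Feature ``k = (i-1)*p + j`` in 1-based terms, i.e. row-major with the
    victim (affected) drug's descriptor index varying slowest.  Length is
    ``p**2``.
    """
    _check_aligned(fa, fb)
    values = np.outer(fa.values, fb.values).ravel()
    names = tuple(
        cross_product_name(ni, nj) for ni in fa.names for nj in fb.names
    )
    return InteractionFeatureVector(pair_id, "cross_product", names, values)


def concat_features(
    fa: DescriptorVector, fb: DescriptorVector, pair_id: str = ""
) -> InteractionFeatureVector:
    """Victim vector followed by perpetrator vector; length ``2p``."""
    _check_aligned(fa, fb)
    values = np.concatenate([fa.values, fb.values])
    names = tuple(f"A:{n}" for n in fa.names) + tuple(f"B:{n}" for n in fb.names)
    return InteractionFeatureVector(pair_id, "concat", names, values)


def sum_product_features(
    fa: DescriptorVector, fb: DescriptorVector, pair_id: str = ""
) -> InteractionFeatureVector:
    """Blocked layout: all elementwise sums, then all elementwise products.

    Positions ``1..p`` hold ``fa[i] + fb[i]`` and positions ``p+1..2p``
    hold ``fa[i] * fb[i]``; length ``2p``.
    """
    _check_aligned(fa, fb)
    values = np.concatenate([fa.values + fb.values, fa.values * fb.values])
    names = tuple(f"sum:{n}" for n in fa.names) + tuple(f"prod:{n}" for n in fa.names)
    return InteractionFeatureVector(pair_id, "sum_product", names, values)


OPERATORS: dict[str, Callable] = {
    "cross_product": cross_product_features,
    "concat": concat_features,
    "sum_product": sum_product_features,
}


def build_pair_feature_matrix(
    drugs: Iterable,
    pairs: Iterable,
    mode: str = "cross_product",
    provider: RDKitDescriptorProvider | None = None,
) -> pd.DataFrame:
    """Feature matrix for ordered (victim, perpetrator) pairs.

    Parameters
    ----------
    drugs
        iterable of objects with ``drug_id`` and ``smiles`` attributes.
    pairs
        iterable of objects with ``victim_id`` and ``perpetrator_id``.
    mode
        one of ``cross_product`` | ``concat`` | ``sum_product``.

    Returns a DataFrame with one row per pair (index ``victim_perpetrator``)
    and one named column per interaction feature.
    """
    if mode not in OPERATORS:
        raise ValueError(f"unknown combination mode {mode!r}")
    provider = provider or default_provider()
    op = OPERATORS[mode]
    vectors = {
        d.drug_id: compute_descriptors(d.smiles, d.drug_id, provider) for d in drugs
    }
    rows, index, names = [], [], None
    for p in pairs:
        fv = op(vectors[p.victim_id], vectors[p.perpetrator_id],
                pair_id=f"{p.victim_id}_{p.perpetrator_id}")
        if names is None:
            names = fv.names
        rows.append(fv.values)
        index.append(fv.pair_id)
    if not rows:
        return pd.DataFrame(columns=list(names or []))
    return pd.DataFrame(np.vstack(rows), index=index, columns=list(names))
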