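"""Synthetic screening data with a learnable top tail.

Real inputs to this workflow are docking screens: millions of fingerprints
paired with energy-like scores whose favorable tail is enriched in
particular substructures. The generator emulates exactly that coupling
without any docking software, in two modes:

* **feature mode** (:func:`generate_screen`) draws binary fingerprint-like
  rows with latent bit-cluster structure. Each of ``n_latent`` clusters of
  bits co-activates as a unit; a fixed random weight per cluster maps the
  activation pattern to a latent druggability value, and the pseudo-docking
  score is an affine map of ``signal_strength * latent + noise`` onto a
  docking-like energy range. Rows are i.i.d., so any train/test split is
  exchangeable by construction — the assumption conformal validity rests on.

* **molecule mode** (:func:`generate_molecule_screen`) enumerates valid
  SMILES from a small fixed fragment grammar (substituted aromatic
  scaffolds) and scores each molecule by a fixed linear function of its
  Morgan fingerprint bits plus seeded noise, exercising the full molecule
  I/O and featurization path.

Both modes are pure functions of their configuration and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chem_io import FeatureMatrix, FingerprintConfig, MoleculeRecord, featurize

__all__ = ["SyntheticScreenConfig", "SyntheticScreen", "generate_screen",
           "generate_molecule_screen", "fragment_score_weights",
           "grammar_capacity"]


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Knobs of the feature-mode generator.

    ``signal_strength`` is the weight of the latent term in the score (the
    latent is standardized to unit variance, so with the default noise_sd of
    0.3 the latent explains ~90% of score variance — a learnable but noisy
    docking surrogate). ``score_offset``/``score_scale`` map the standardized
    score onto a docking-like kcal/mol range; all downstream logic is
    affine-invariant, the range is cosmetic.
    """

    n_compounds: int = 10_000
    n_bits: int = 1024
    n_latent: int = 16
    signal_strength: float = 1.0
    noise_sd: float = 0.3
    score_offset: float = -30.0
    score_scale: float = 10.0
    active_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 100:
            raise ValueError("n_compounds must be >= 100")
        if not 0.0 < self.active_fraction < 0.5:
            raise ValueError("active_fraction must lie in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_latent < 1 or self.n_latent > self.n_bits:
            raise ValueError("need 1 <= n_latent <= n_bits")


@dataclass
class SyntheticScreen:
    """Features, pseudo-docking scores, and (diagnostic-only) latents."""

    features: FeatureMatrix
    scores: np.ndarray
    true_latent: np.ndarray
    config: SyntheticScreenConfig

    @property
    def ids(self) -> list[str]:
        return self.features.ids

    def __len__(self) -> int:
        return len(self.features.ids)


# probability a cluster's bits fire when the cluster is (in)active; chosen so
# cluster state is recoverable from the bits but individual bits stay noisy
_BIT_P_ON = 0.85
_BIT_P_OFF = 0.03
_BACKGROUND_P = 0.05


def generate_screen(config: SyntheticScreenConfig) -> SyntheticScreen:
    """Draw an i.i.d. synthetic screen from the bit-cluster model.

    Bits are grouped into ``n_latent`` equal contiguous clusters (leftover
    bits fire independently as background). Per compound, cluster j
    activates with probability p_j ~ U(0.05, 0.3); active clusters light
    their bits with probability 0.85, inactive with 0.03. The latent value
    is a fixed N(0,1)-weighted sum of cluster activations, standardized, and

        score = offset - scale * (signal_strength * latent + N(0, noise_sd))

    so high-latent compounds get the most negative (best) scores. Identical
    config (including seed) reproduces the screen byte for byte.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_bits // cfg.n_latent
    p_act = rng.uniform(0.05, 0.3, size=cfg.n_latent)
    w = rng.normal(0.0, 1.0, size=cfg.n_latent)

    z = rng.random((cfg.n_compounds, cfg.n_latent)) < p_act
    bits = np.zeros((cfg.n_compounds, cfg.n_bits), dtype=np.uint8)
    u = rng.random((cfg.n_compounds, cfg.n_bits))
    for j in range(cfg.n_latent):
        cols = slice(j * m, (j + 1) * m)
        p = np.where(z[:, j], _BIT_P_ON, _BIT_P_OFF)
        bits[:, cols] = (u[:, cols] < p[:, None]).astype(np.uint8)
    if cfg.n_latent * m < cfg.n_bits:
        cols = slice(cfg.n_latent * m, cfg.n_bits)
        bits[:, cols] = (u[:, cols] < _BACKGROUND_P).astype(np.uint8)

    raw = z @ w
    mean = float(np.dot(w, p_act))
    var = float(np.dot(w**2, p_act * (1.0 - p_act)))
    latent = (raw - mean) / np.sqrt(var)
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_compounds)
    scores = cfg.score_offset - cfg.score_scale * (
        cfg.signal_strength * latent + noise)

    ids = [f"SYN-{i:07d}" for i in range(cfg.n_compounds)]
    fm = FeatureMatrix(ids=ids, bits=bits, config=None)
    return SyntheticScreen(features=fm, scores=scores, true_latent=latent,
                           config=cfg)


# ---------------------------------------------------------------------------
# molecule mode: a tiny fragment grammar of disubstituted aromatic scaffolds

_SCAFFOLDS = [
    "c1ccc({a})cc1{b}",      # benzene
    "c1ccc({a})nc1{b}",      # pyridine
    "c1cc({a})sc1{b}",       # thiophene
    "c1cc({a})oc1{b}",       # furan
    "c1cc({a})[nH]c1{b}",    # pyrrole
    "c1nc({a})cc({b})n1",    # pyrimidine
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(=O)OC", "C(=O)NC",
    "S(C)(=O)=O", "CO", "C=C",
]

_MOLECULE_FP = FingerprintConfig(radius=2, n_bits=1024)
_WEIGHT_MASTER_SEED = 941_223_017  # fixed: bit weights are part of the grammar


def grammar_capacity() -> int:
    """Number of distinct molecules the fragment grammar can emit."""
    return len(_SCAFFOLDS) * len(_SUBSTITUENTS) ** 2


def fragment_score_weights(n_bits: int = _MOLECULE_FP.n_bits) -> np.ndarray:
    """Fixed per-bit score weights of the molecule-mode scoring function.

    Deterministic and independent of the library seed, so the noiseless
    score of any molecule can be recomputed as ``-30 - bits @ weights``.
    """
    rng = np.random.default_rng(_WEIGHT_MASTER_SEED)
    return rng.normal(0.0, 0.25, size=n_bits)


def generate_molecule_screen(n: int, seed: int, noise_sd: float = 0.5,
                             ) -> tuple[list[MoleculeRecord], np.ndarray]:
    """Sample n distinct molecules from the grammar with pseudo-docking scores.

    score = -30 - (fingerprint bits @ fixed weights) + N(0, noise_sd).
    Every emitted SMILES is valid by construction. Raises if ``n`` exceeds
    the grammar's capacity (reported in the message).
    """
    cap = grammar_capacity()
    if n > cap:
        raise ValueError(f"n={n} exceeds grammar capacity of {cap} molecules")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    combos = list(itertools.product(range(len(_SCAFFOLDS)),
                                    range(len(_SUBSTITUENTS)),
                                    range(len(_SUBSTITUENTS))))
    chosen = rng.choice(len(combos), size=n, replace=False)
    records = []
    for idx in chosen:
        s, a, b = combos[idx]
        smiles = _SCAFFOLDS[s].format(a=_SUBSTITUENTS[a], b=_SUBSTITUENTS[b])
        records.append(MoleculeRecord(id=f"MOL-{s}-{a}-{b}", smiles=smiles))
    fm = featurize(records, _MOLECULE_FP)
    if fm.failed_ids:  # grammar guarantee; never expected
        raise RuntimeError(f"grammar emitted unparseable SMILES: {fm.failed_ids}")
    w = fragment_score_weights(_MOLECULE_FP.n_bits)
    scores = -30.0 - fm.bits.astype(float) @ w
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=n)
    return records, scores
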