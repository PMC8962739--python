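"""Chemical-similarity evaluation of generated molecules.

Generated molecules are scored against a pocket's label ligand with the
Tanimoto coefficient TC = |A∩B| / |A∪B| over binary substructure
fingerprints (default: circular/Morgan, radius 2, 2048 bits — the
community-standard choice; absolute TC values depend on this and the
config is swappable). Per pocket the *maximum* TC over the sampled set
is the final score; hit rates report the percentage of pockets whose
score reaches thresholds 0.7/0.8/0.9/1.0. Group comparisons use the
Fisher–Pitman permutation test on the difference of group means
(exhaustive over label assignments when feasible, Monte-Carlo
otherwise). Size statistics mirror the pocket-size quartile analysis:
pockets are binned at <100, 100–160, 161–220 and >220 heavy atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

from .grammar import canonical_smiles

TC_THRESHOLDS = (0.7, 0.8, 0.9, 1.0)
POCKET_SIZE_BINS = ((0, 99), (100, 160), (161, 220), (221, None))


@dataclass(frozen=True)
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 2048


_GENERATORS: dict[FingerprintConfig, object] = {}


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str, config: FingerprintConfig = FingerprintConfig()):
    if config not in _GENERATORS:
        _GENERATORS[config] = rdFingerprintGenerator.GetMorganGenerator(
            radius=config.radius, fpSize=config.n_bits)
    return _GENERATORS[config].GetFingerprint(_mol(smiles))


def fingerprint_bits(smiles: str, config: FingerprintConfig = FingerprintConfig()) -> set[int]:
    """Explicit on-bit set (the slow route used as a cross-check)."""
    return set(fingerprint(smiles, config).GetOnBits())


def tanimoto(smiles_a: str, smiles_b: str,
             config: FingerprintConfig = FingerprintConfig()) -> float:
    """TC between two molecules' fingerprints; symmetric, in [0, 1]."""
    return float(TanimotoSimilarity(fingerprint(smiles_a, config),
                                    fingerprint(smiles_b, config)))


@dataclass(frozen=True)
class TcScore:
    pocket_id: str
    best_tc: float
    best_molecule: str


def max_tc_score(samples, label_smiles: str, pocket_id: str = "",
                 config: FingerprintConfig = FingerprintConfig()) -> TcScore:
    """Highest TC over a sampled set (ties → first in canonical order)."""
    samples = sorted(set(samples))
    if not samples:
        raise ValueError("empty sample set")
    label_fp = fingerprint(label_smiles, config)
    best_tc, best_mol = -1.0, ""
    for smi in samples:
        tc = float(TanimotoSimilarity(fingerprint(smi, config), label_fp))
        if tc > best_tc:
            best_tc, best_mol = tc, smi
    return TcScore(pocket_id=pocket_id, best_tc=best_tc, best_molecule=best_mol)


@dataclass
class HitRateReport:
    rates: dict[float, float]   # threshold → percentage of pockets
    n_pockets: int
    sample_size: int | None = None
    method: str = ""

    def to_dict(self) -> dict:
        return {"method": self.method, "n_pockets": self.n_pockets,
                "sample_size": self.sample_size,
                "rates": {f"TC>={t:g}": r for t, r in self.rates.items()}}


def hit_rates(scores: list[TcScore], thresholds=TC_THRESHOLDS,
              sample_size: int | None = None, method: str = "") -> HitRateReport:
    """Percentage of pockets whose best score reaches each threshold."""
    if not scores:
        raise ValueError("no scores")
    best = np.array([s.best_tc for s in scores])
    rates = {float(t): float(100.0 * np.mean(best >= t)) for t in thresholds}
    return HitRateReport(rates=rates, n_pockets=len(scores),
                         sample_size=sample_size, method=method)


def fisher_pitman(group_a, group_b, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the difference of group means.

    Exhaustive over all label assignments when their count is at most
    ``n_perm``; otherwise Monte-Carlo with the observed assignment
    included (add-one estimator, so p is never 0).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    total = pooled.sum()
    observed = abs(a.mean() - b.mean())
    tol = 1e-12 * max(1.0, abs(observed))

    def diff_from_sum(sum_a):
        return np.abs(sum_a / na - (total - sum_a) / (n - na))

    n_assign = math.comb(n, na)
    if n_assign <= n_perm:
        hits = 0
        for idx in combinations(range(n), na):
            if diff_from_sum(pooled[list(idx)].sum()) >= observed - tol:
                hits += 1
        return hits / n_assign
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if diff_from_sum(perm[:na].sum()) >= observed - tol:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def ligand_size(smiles: str) -> int:
    """Number of heavy (non-hydrogen) atoms in a molecule."""
    return _mol(smiles).GetNumHeavyAtoms()


@dataclass
class SizeGroupStats:
    bins: tuple = POCKET_SIZE_BINS
    stats: dict = field(default_factory=dict)  # bin label → quartile dict


def _bin_label(lo, hi) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == 0:
        return f"<{hi + 1}"
    return f"{lo}-{hi}"


def size_group_stats(pairs) -> SizeGroupStats:
    """Quartiles of ligand heavy-atom counts per pocket-size bin.

    ``pairs`` are (pocket_heavy_atoms, ligand_heavy_atoms) tuples;
    quartiles use linear interpolation.
    """
    out = SizeGroupStats()
    for lo, hi in POCKET_SIZE_BINS:
        sizes = [lig for poc, lig in pairs
                 if poc >= lo and (hi is None or poc <= hi)]
        label = _bin_label(lo, hi)
        if not sizes:
            out.stats[label] = None
            continue
        q1, q2, q3 = np.percentile(sizes, [25, 50, 75], method="linear")
        out.stats[label] = {"n": len(sizes), "q1": float(q1), "median": float(q2),
                            "q3": float(q3), "iqr": float(q3 - q1)}
    return out
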