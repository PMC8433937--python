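"""Synthetic drug-target worlds with a plantable interaction signal.

Real benchmarks need PSI-BLAST profiles and curated interaction lists;
for testing, this module fabricates all three inputs with known ground
truth.  Drugs and proteins carry latent compatibility vectors u_d and
v_p; a pair interacts with probability sigmoid(s * <u_d, v_p> / sqrt(k)
+ b), with the bias b solved so the expected positive fraction matches
``positive_rate``.  The latent vectors leak into the observable data on
both sides:

* fingerprint bits are noisy threshold readouts of random projections
  of u_d, so the drug's half of the descriptor carries its latent
  coordinates;
* each protein's PSSM is an AR(1)-smoothed random profile (adjacent
  rows correlated, rho = 0.7, integer scores in the PSI-BLAST-like
  range [-10, 12]) *modulated* by smooth row x column patterns whose
  amplitudes are the components of v_p, so the pooled wavelet features
  carry the protein's latent coordinates.

A pipeline that recovers held-out interactions above chance on such a
world is demonstrably reading signal out of both modalities; after
label permutation it must fall back to AUC 0.5.

Latent coordinates are drawn around a positive mean (``latent_mean``),
modelling a dominant affinity axis (generally druggable proteins,
generally promiscuous compounds) on top of which the per-dimension
compatibility acts; the interaction probability is still the bilinear
logistic form above.

The default world — 60 drugs x 50 proteins, latent dimension 2, signal
strength 3, positive rate 0.1 (about 300 positive pairs) — is sized
near the smaller gold-standard collections while keeping a full
cross-validation run fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .fingerprints import N_BITS, DrugFingerprint, render_fingerprints
from .pssm import CANONICAL_ALPHABET, PSSM
from .pipeline import InteractionSet

__all__ = ["SimConfig", "gen_pssm", "render_pssm", "gen_fingerprints",
           "gen_dti_world", "write_world"]

SCORE_MIN, SCORE_MAX = -10, 12
_AR_RHO = 0.7


@dataclass(frozen=True)
class SimConfig:
    n_drugs: int = 60
    n_proteins: int = 50
    protein_length_range: tuple[int, int] = (40, 200)
    latent_dim: int = 2
    latent_mean: float = 1.0
    signal_strength: float = 3.0
    positive_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("world must contain at least one drug and protein")
        lo, hi = self.protein_length_range
        if lo < 8 or hi < lo:
            raise ValueError("protein_length_range minimum must be >= 8")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")


def _ar1_profile(n: int, rng: np.random.Generator, rho: float = _AR_RHO) -> np.ndarray:
    """Stationary AR(1) series, unit marginal variance."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1 - rho ** 2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def _pssm_matrix(length: int, rng: np.random.Generator,
                 signal: np.ndarray | None = None) -> np.ndarray:
    """Integer score matrix: AR(1) row profile x column loading + noise."""
    profile = _ar1_profile(length, rng) * 4.0
    col_load = 0.5 + rng.random(20)
    noise = rng.standard_normal((length, 20)) * 1.5
    raw = profile[:, None] * col_load[None, :] + noise
    if signal is not None:
        raw = raw + signal
    return np.clip(np.rint(raw), SCORE_MIN, SCORE_MAX)


def gen_pssm(length: int, seed: int, protein_id: str = "synthetic") -> PSSM:
    """Random PSI-BLAST-like profile; deterministic per (length, seed)."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    matrix = _pssm_matrix(length, rng)
    residues = "".join(rng.choice(list(CANONICAL_ALPHABET), size=length))
    return PSSM(protein_id=protein_id, matrix=matrix, residues=residues)


def render_pssm(p: PSSM) -> str:
    """Emit the PSI-BLAST ``-out_ascii_pssm`` dialect (parse round-trip)."""
    letters = " ".join(p.column_order)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + letters + "   " + letters,
    ]
    for i, (res, row) in enumerate(zip(p.residues, np.asarray(p.matrix)), start=1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        pct = " ".join("  0" for _ in row)
        lines.append(f"{i:5d} {res}  {scores}  {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.1337     0.3113", ""]
    return "\n".join(lines)


def gen_fingerprints(n: int, seed: int, prefix: str = "D",
                     density: float = 0.15) -> dict[str, DrugFingerprint]:
    """Independent random fingerprints (bit density like sparse keysets)."""
    rng = np.random.default_rng(seed)
    return {
        f"{prefix}{i + 1:05d}": DrugFingerprint(
            f"{prefix}{i + 1:05d}", (rng.random(N_BITS) < density).astype(np.uint8))
        for i in range(n)
    }


def _latent_fingerprints(U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bits = sign readouts of random projections of each drug's latents."""
    n, k = U.shape
    proj = rng.standard_normal((N_BITS, k)) / np.sqrt(k)
    noise = rng.standard_normal((n, N_BITS)) * 0.3
    return (U @ proj.T + noise > 0).astype(np.uint8)


def _latent_signal(length: int, v: np.ndarray, col_patterns: np.ndarray,
                   scale: float = 4.0) -> np.ndarray:
    """Smooth row x column modulation with per-latent amplitude v."""
    k = v.size
    t = np.linspace(0.0, np.pi, length)
    rows = np.stack([np.cos((j + 1) * t) for j in range(k)])        # (k, length)
    return scale * np.einsum("j,jl,jc->lc", v, rows, col_patterns)


def gen_dti_world(cfg: SimConfig) -> tuple[
        InteractionSet, dict[str, DrugFingerprint], dict[str, PSSM], dict]:
    """Generate an interaction graph, fingerprints and PSSMs with truth.

    Returns (interactions, fingerprints, pssms, truth); ``truth`` holds
    the latent vectors, the pairwise logit scores and the solved bias.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.latent_dim
    U = cfg.latent_mean + rng.standard_normal((cfg.n_drugs, k))
    V = cfg.latent_mean + rng.standard_normal((cfg.n_proteins, k))
    drug_ids = [f"D{i + 1:05d}" for i in range(cfg.n_drugs)]
    prot_ids = [f"hsa{i + 1:04d}" for i in range(cfg.n_proteins)]

    bits = _latent_fingerprints(U, rng)
    fingerprints = {d: DrugFingerprint(d, bits[i]) for i, d in enumerate(drug_ids)}

    col_patterns = rng.standard_normal((k, 20)) / np.sqrt(20)
    lo, hi = cfg.protein_length_range
    pssms: dict[str, PSSM] = {}
    for j, pid in enumerate(prot_ids):
        length = int(rng.integers(lo, hi + 1))
        signal = _latent_signal(length, V[j], col_patterns)
        matrix = _pssm_matrix(length, rng, signal=signal)
        residues = "".join(rng.choice(list(CANONICAL_ALPHABET), size=length))
        pssms[pid] = PSSM(protein_id=pid, matrix=matrix, residues=residues)

    scores = cfg.signal_strength * (U @ V.T) / np.sqrt(k)

    def excess(b: float) -> float:
        return float(expit(scores + b).mean() - cfg.positive_rate)

    bias = brentq(excess, -50.0, 50.0)
    prob = expit(scores + bias)
    hits = rng.random(prob.shape) < prob
    positives = {(drug_ids[i], prot_ids[j]) for i, j in zip(*np.nonzero(hits))}
    interactions = InteractionSet(drugs=drug_ids, proteins=prot_ids,
                                  positives=positives)
    truth = {"U": U, "V": V, "scores": scores, "bias": bias,
             "probabilities": prob}
    return interactions, fingerprints, pssms, truth


def write_world(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a world on disk in the formats the pipeline consumes."""
    out = Path(out_dir)
    (out / "pssms").mkdir(parents=True, exist_ok=True)
    interactions, fingerprints, pssms, _ = gen_dti_world(cfg)
    paths = {
        "interactions": out / "interactions.tsv",
        "fingerprints": out / "fingerprints.tsv",
        "pssm_dir": out / "pssms",
    }
    interactions.to_table(paths["interactions"])
    paths["fingerprints"].write_text(render_fingerprints(fingerprints))
    for pid, p in pssms.items():
        (out / "pssms" / f"{pid}.pssm").write_text(render_pssm(p))
    return paths
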