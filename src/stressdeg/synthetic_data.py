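"""Negative-binomial count simulator emulating the drying time-course design.

Counts follow NB(mean, dispersion) with variance mu + alpha*mu^2 per gene.
A configurable fraction of genes is planted as differentially expressed in
one to four genotypes; each planted gene carries a 3-letter trajectory
archetype under against-reference (AR) semantics (letters give the sign of
the log2 shift at EWC 15, 5 and 1 relative to the 35 % baseline).  The
ground truth — codes, signed shifts, genotype sharing and cross-genotype
direction concordance — is returned as a tidy ledger so every downstream
stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import EWC_POINTS, TISSUES, CountMatrix, SampleMeta, ValidationError

GENOTYPES_DEFAULT = ("Ba12", "Ba99", "Bf11", "p194")

# Archetype weights loosely follow the observed prevalence of single-step
# late responses (nnd/nnu), early responses (dnn/unn) and monotone sustained
# responses (ddd/uuu) in bulk drying time courses.
ARCHETYPE_WEIGHTS_DEFAULT: dict[str, float] = {
    "nnd": 0.22, "nnu": 0.22,
    "ndd": 0.13, "nuu": 0.13,
    "ddd": 0.08, "uuu": 0.08,
    "dnn": 0.05, "unn": 0.05,
    "und": 0.02, "dnu": 0.02,
}

# P(planted gene is DE in exactly k genotypes), k = 1..4.
SHARING_WEIGHTS_DEFAULT = (0.35, 0.2, 0.15, 0.3)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated drying experiment."""

    n_genes: int = 2000
    genotypes: tuple[str, ...] = GENOTYPES_DEFAULT
    tissues: tuple[str, ...] = TISSUES
    ewc_points: tuple[int, ...] = EWC_POINTS
    n_reps: int = 4
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)  # log2 scale
    dispersion: float = 0.1  # NB alpha; variance = mu + alpha mu^2
    planted_fraction: float = 0.1
    archetype_weights: dict[str, float] = field(
        default_factory=lambda: dict(ARCHETYPE_WEIGHTS_DEFAULT)
    )
    sharing_weights: tuple[float, ...] = SHARING_WEIGHTS_DEFAULT
    mixed_prob: float = 0.25  # P(direction flipped in a strict subset of carriers)
    effect_size: float = 2.0  # |log2 fold change| of planted shifts
    library_size_range: tuple[float, float] = (0.5e6, 1.5e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValidationError("n_reps must be >= 2 for DE testing")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValidationError("planted_fraction must lie in [0, 1]")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        total = sum(self.archetype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"archetype_weights sum to {total}, not 1")
        for code in self.archetype_weights:
            _check_code(code)
        if len(self.sharing_weights) < len(self.genotypes):
            raise ValidationError(
                "sharing_weights needs at least one entry per genotype")

    def effective_sharing_weights(self) -> np.ndarray:
        """Weights over 1..n_genotypes carriers, renormalized (extra tail
        entries of the default 4-genotype weights are dropped when fewer
        genotypes are simulated)."""
        w = np.asarray(self.sharing_weights[: len(self.genotypes)], dtype=float)
        return w / w.sum()


def _check_code(code: str) -> None:
    if len(code) != 3 or any(c not in "nud" for c in code):
        raise ValidationError(f"invalid trajectory code {code!r}")


def plant_trajectory(code: str, effect_size: float) -> tuple[float, float, float]:
    """Signed log2 shifts at EWC 15, 5, 1 (vs 35) for a 3-letter AR code.

    n -> 0, u -> +effect_size, d -> -effect_size per position.
    """
    _check_code(code)
    if effect_size <= 0:
        raise ValidationError("effect_size must be positive")
    lut = {"n": 0.0, "u": effect_size, "d": -effect_size}
    return tuple(lut[c] for c in code)  # type: ignore[return-value]


def tc_code_from_shifts(shifts: tuple[float, float, float]) -> str:
    """Derive the TC-semantics ground-truth code from AR shifts.

    The TC comparisons are 35/15, 15/5, 5/1; the planted log2 change at each
    is the difference between consecutive per-EWC shifts (with 0 at 35 %).
    """
    deltas = (shifts[0], shifts[1] - shifts[0], shifts[2] - shifts[1])
    return "".join("n" if d == 0 else ("u" if d > 0 else "d") for d in deltas)


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one experiment; returns (CountMatrix, truth ledger).

    The ledger has one row per gene x genotype x tissue with columns
    gene_id, genotype, tissue, planted_code_AR, planted_code_TC, shift_15,
    shift_5, shift_1, n_genotypes, concordance ({concordant, mixed}; genes
    never planted carry code nnn and concordance 'none').

    Identical config + seed reproduces identical counts bit-exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genos = list(config.genotypes)
    gene_ids = [f"g{i:05d}" for i in range(G)]

    base_log2 = rng.uniform(*config.baseline_log_mean_range, size=G)
    baseline = 2.0 ** base_log2

    n_planted = int(round(config.planted_fraction * G))
    planted_idx = rng.choice(G, size=n_planted, replace=False) if n_planted else np.array([], int)
    codes = list(config.archetype_weights)
    probs = np.array([config.archetype_weights[c] for c in codes])

    # shift[g, genotype, ewc_index] on log2 scale (ewc order = config.ewc_points)
    shift = np.zeros((G, len(genos), len(config.ewc_points)))
    truth_rows = []
    planted_info: dict[int, dict] = {}
    for gi in planted_idx:
        code = codes[rng.choice(len(codes), p=probs)]
        shifts = plant_trajectory(code, config.effect_size)
        k = 1 + rng.choice(len(genos), p=config.effective_sharing_weights())
        carriers = sorted(rng.choice(len(genos), size=k, replace=False))
        flipped: set[int] = set()
        if k >= 2 and rng.random() < config.mixed_prob:
            # flip sign of all shifts in a strict non-empty subset of carriers
            n_flip = int(rng.integers(1, k))
            flipped = set(rng.choice(carriers, size=n_flip, replace=False).tolist())
        for ci in carriers:
            sgn = -1.0 if ci in flipped else 1.0
            for ei, e in enumerate(config.ewc_points):
                if e == 35:
                    continue
                pos = {15: 0, 5: 1, 1: 2}[e]
                shift[gi, ci, ei] = sgn * shifts[pos]
        planted_info[int(gi)] = {
            "code": code, "shifts": shifts, "carriers": carriers, "flipped": flipped,
        }

    # sample grid and target library sizes
    samples: list[SampleMeta] = []
    for t in config.tissues:
        for g in genos:
            for e in config.ewc_points:
                for r in range(1, config.n_reps + 1):
                    samples.append(SampleMeta(f"{g}_{t}_e{e}_r{r}", g, t, e, r))
    lo, hi = config.library_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    counts = np.empty((G, len(samples)), dtype=np.int64)
    geno_index = {g: i for i, g in enumerate(genos)}
    ewc_index = {e: i for i, e in enumerate(config.ewc_points)}
    alpha = config.dispersion
    for j, s in enumerate(samples):
        mu = baseline * 2.0 ** shift[:, geno_index[s.genotype], ewc_index[s.ewc]]
        mu = mu * (lib_sizes[j] / mu.sum())
        if alpha > 0:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, j] = rng.poisson(mu)

    df = pd.DataFrame(counts, index=gene_ids,
                      columns=[s.sample_id for s in samples])
    cm = CountMatrix(gene_ids, samples, df)

    for gi in range(G):
        info = planted_info.get(gi)
        for t in config.tissues:
            for ci, g in enumerate(genos):
                if info is None or ci not in info["carriers"]:
                    code_ar, sh, conc = "nnn", (0.0, 0.0, 0.0), "none"
                else:
                    sgn = -1.0 if ci in info["flipped"] else 1.0
                    sh = tuple(sgn * x for x in info["shifts"])
                    code_ar = "".join(
                        "n" if x == 0 else ("u" if x > 0 else "d") for x in sh
                    )
                    conc = "mixed" if info["flipped"] else "concordant"
                truth_rows.append({
                    "gene_id": gene_ids[gi], "genotype": g, "tissue": t,
                    "planted_code_AR": code_ar,
                    "planted_code_TC": tc_code_from_shifts(sh),
                    "shift_15": sh[0], "shift_5": sh[1], "shift_1": sh[2],
                    "n_genotypes": 0 if info is None else len(info["carriers"]),
                    "concordance": conc,
                })
    ledger = pd.DataFrame(truth_rows)
    return cm, ledger


def null_config(**overrides) -> SimConfig:
    """Convenience: a no-planted-genes configuration (pure noise)."""
    return replace(SimConfig(planted_fraction=0.0), **overrides)
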