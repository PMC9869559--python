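"""Synthetic inputs for offline testing of the pipeline.

Two generators live here:

* :func:`simulate_counts` draws RNA-seq-like count matrices from a
  negative binomial parameterized by mean and dispersion
  (variance = mu + alpha * mu^2, the standard RNA-seq noise model),
  with fold changes planted on designated gene sets — a stand-in for
  the deposited expression matrices, emulating two-group contrasts at
  the thresholds used for the overlay stage.
* :func:`simulate_network` builds small random stoichiometric networks
  (mass-consistent under synthetic one-element formulas, one uptake and
  one secretion exchange, guaranteed nonzero optimum) used to validate
  the LP layer against brute-force vertex enumeration.

Both are pure functions of their spec, seed included: identical specs
give byte-identical outputs.  :func:`naive_de_table` is a deliberately
simple synthetic DE summary (Welch t on log counts + BH adjustment),
not a reimplementation of a shrinkage-based DE fitter; it exists so the
overlay stage has a self-contained input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    Metabolite,
    ModelValidationError,
    Reaction,
    StoichiometricModel,
    serialize_metabolite_table,
    serialize_reaction_table,
)

__all__ = [
    "CountSimSpec",
    "RandomNetSpec",
    "simulate_counts",
    "simulate_network",
    "naive_de_table",
    "make_fixture_suite",
]


@dataclass
class CountSimSpec:
    """Specification of a two-group planted-DE count simulation.

    ``planted_log2fc`` is applied as +fc to ``planted_up`` and -fc to
    ``planted_down`` genes in the contrast group.  Per-sample library
    size factors are drawn log-uniform in [0.7, 1.3] to exercise
    normalization code.  ``mean_expression_log_range`` is the log10
    range of baseline means.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 3
    planted_up: tuple[str, ...] = ()
    planted_down: tuple[str, ...] = ()
    planted_log2fc: float = 2.0
    dispersion: float = 0.05
    mean_expression_log_range: tuple[float, float] = (1.0, 3.0)
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ModelValidationError("n_genes must be >= 1")
        if self.n_samples_per_group < 2:
            raise ModelValidationError("n_samples_per_group must be >= 2")
        if self.dispersion <= 0:
            raise ModelValidationError("dispersion must be > 0")
        if self.planted_log2fc < 0:
            raise ModelValidationError("planted_log2fc must be >= 0")
        if set(self.planted_up) & set(self.planted_down):
            raise ModelValidationError("planted up/down sets must be disjoint")
        lo, hi = self.mean_expression_log_range
        if hi < lo:
            raise ModelValidationError("mean_expression_log_range must be ordered")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ModelValidationError("gene_ids length must equal n_genes")


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """NB(mean mu, variance mu + alpha mu^2) via numpy's (n, p) form."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix plus its ground truth.

    Returns ``(counts, truth)``: counts with sample columns
    ``ref_1..ref_k, alt_1..alt_k`` (reference vs contrast group), and a
    truth table with columns gene_id, true_log2fc, planted
    (up/down/none) and the baseline mean.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = (
        list(spec.gene_ids)
        if spec.gene_ids is not None
        else [f"g{i:05d}" for i in range(spec.n_genes)]
    )
    for g in list(spec.planted_up) + list(spec.planted_down):
        if g not in genes:
            raise ModelValidationError(f"planted gene {g} not in gene id set")
    lo, hi = spec.mean_expression_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=spec.n_genes)
    fc = np.zeros(spec.n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    for g in spec.planted_up:
        fc[gi[g]] = spec.planted_log2fc
    for g in spec.planted_down:
        fc[gi[g]] = -spec.planted_log2fc

    k = spec.n_samples_per_group
    samples = [f"ref_{i+1}" for i in range(k)] + [f"alt_{i+1}" for i in range(k)]
    size_factors = np.exp(rng.uniform(np.log(0.7), np.log(1.3), size=2 * k))
    counts = np.empty((spec.n_genes, 2 * k), dtype=np.int64)
    for s in range(2 * k):
        mu = base_mean * size_factors[s]
        if s >= k:
            mu = mu * 2.0 ** fc
        counts[:, s] = _nb_draw(rng, mu, spec.dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    planted = np.where(fc > 0, "up", np.where(fc < 0, "down", "none"))
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_log2fc": fc,
            "planted": planted,
            "base_mean": base_mean,
        }
    )
    return counts_df, truth


def naive_de_table(counts: pd.DataFrame, n_reference: int) -> pd.DataFrame:
    """Summarize a two-group count matrix into a DESeq2-shaped table.

    Median-of-ratios size factors, log2 ratio of normalized group means
    (with a 0.5 pseudocount), a moderated z-test on log2(normalized + 1)
    whose variance is pooled across all genes (small-sample designs have
    too few replicates for stable per-gene variances), and
    Benjamini-Hochberg adjustment.  Synthetic plumbing for tests — not a
    dispersion-shrinkage DE method.
    """
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    ref = logs.mean(axis=1, keepdims=True)
    finite = np.isfinite(ref).ravel()
    ratios = logs[finite] - ref[finite]
    size_factors = np.exp(np.median(ratios, axis=0))
    norm = values / size_factors
    a, b = norm[:, :n_reference], norm[:, n_reference:]
    log2fc = np.log2((b.mean(axis=1) + 0.5) / (a.mean(axis=1) + 0.5))
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    pooled_var = 0.5 * (la.var(axis=1, ddof=1).mean() + lb.var(axis=1, ddof=1).mean())
    se = np.sqrt(pooled_var * (1.0 / la.shape[1] + 1.0 / lb.shape[1]))
    z = (lb.mean(axis=1) - la.mean(axis=1)) / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = stats.false_discovery_control(pvals, method="bh")
    return pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "log2FoldChange": log2fc,
            "padj": padj,
            "baseMean": norm.mean(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# Random stoichiometric networks
# ---------------------------------------------------------------------------

@dataclass
class RandomNetSpec:
    """Specification of a small random metabolic network.

    The network is a chain backbone m1 -> ... -> mM (uptake exchange on
    m1, secretion on mM, so a nonzero optimum exists by construction)
    plus random extra conversions; every internal reaction conserves the
    synthetic one-atom element X.
    """

    n_metabolites: int = 6
    n_reactions: int = 10
    reversibility_prob: float = 0.3
    seed: int = 0
    uptake_bound: float = 10.0

    def validate(self) -> None:
        if not (self.n_reactions >= self.n_metabolites >= 2):
            raise ModelValidationError(
                "need n_reactions >= n_metabolites >= 2"
            )
        if not (0 <= self.reversibility_prob <= 1):
            raise ModelValidationError("reversibility_prob must be in [0, 1]")


def simulate_network(spec: RandomNetSpec) -> StoichiometricModel:
    """Generate a random, feasible, mass-consistent toy network."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    M, R = spec.n_metabolites, spec.n_reactions
    model = StoichiometricModel(id=f"randomnet_seed{spec.seed}")
    mets = [f"m{i+1}_c" for i in range(M)]
    for mid in mets:
        model.add_metabolite(Metabolite(id=mid, formula={"X": 1.0}, charge=0))

    # exchange convention: "1 met ->", negative flux = uptake
    model.add_reaction(
        Reaction(
            "EX_src",
            {mets[0]: -1.0},
            lower_bound=-spec.uptake_bound,
            upper_bound=0.0,
            subsystem="EXCHANGE",
        )
    )
    model.add_reaction(
        Reaction(
            "EX_snk",
            {mets[-1]: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="EXCHANGE",
        )
    )
    # chain backbone guarantees a path from uptake to secretion
    n_backbone = M - 1
    for i in range(n_backbone):
        rev = rng.random() < spec.reversibility_prob
        model.add_reaction(
            Reaction(
                f"B{i+1}",
                {mets[i]: -1.0, mets[i + 1]: 1.0},
                lower_bound=-1000.0 if rev else 0.0,
                upper_bound=1000.0,
                subsystem="SYNTHETIC",
            )
        )
    n_extra = R - n_backbone  # n_reactions counts internal reactions only
    made = 0
    attempt = 0
    while made < n_extra:
        attempt += 1
        if attempt > 100 * n_extra + 100:
            raise ModelValidationError(
                f"network construction stalled (seed {spec.seed})"
            )
        kind = rng.integers(0, 3)
        if kind == 0 or M < 3:  # 1:1 conversion
            i, j = rng.choice(M, size=2, replace=False)
            stoich = {mets[i]: -1.0, mets[j]: 1.0}
        elif kind == 1:  # condensation a + b -> 2c
            i, j, k = rng.choice(M, size=3, replace=False)
            stoich = {mets[i]: -1.0, mets[j]: -1.0, mets[k]: 2.0}
        else:  # cleavage 2a -> b + c
            i, j, k = rng.choice(M, size=3, replace=False)
            stoich = {mets[i]: -2.0, mets[j]: 1.0, mets[k]: 1.0}
        rev = rng.random() < spec.reversibility_prob
        made += 1
        model.add_reaction(
            Reaction(
                f"R{made}",
                stoich,
                lower_bound=-1000.0 if rev else 0.0,
                upper_bound=1000.0,
                subsystem="SYNTHETIC",
            )
        )
    model.objective = {"EX_snk": 1.0}
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

_WEIMBERG_PLANT_GENES = ("Mtxyd1", "xylD", "xylX", "xylA", "ksaD", "BxxylX")
_GROWTH_PLANT_GENES = ("pgk1", "eno1", "tkl1", "cit1", "rpe1")


def make_fixture_suite(outdir, seed: int = 20230123) -> dict:
    """Write the deterministic fixture suite and its manifest.

    Contents: the shipped core model tables, a synthetic DE table over
    the core model's gene namespace with upregulation planted on the
    Weimberg-route genes (plus a few growth genes, mimicking the
    growth-gene induction seen in Weimberg-carrying strains), and three
    random toy networks.  The manifest records seeds and sha256 sums;
    regenerating with the same seed reproduces every file byte for byte.
    """
    from .model import load_core_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    core = load_core_model()
    (outdir / "core_reactions.tsv").write_text(serialize_reaction_table(core))
    (outdir / "core_metabolites.tsv").write_text(serialize_metabolite_table(core))

    genes = sorted({g for r in core.reactions.values() for g in r.genes()})
    planted_up = tuple(
        g for g in genes if g in _WEIMBERG_PLANT_GENES + _GROWTH_PLANT_GENES
    )
    planted_down = ("Mtxyl1",) if "Mtxyl1" in genes else ()
    spec = CountSimSpec(
        n_genes=len(genes),
        n_samples_per_group=3,
        planted_up=planted_up,
        planted_down=planted_down,
        planted_log2fc=2.0,
        dispersion=0.05,
        mean_expression_log_range=(2.0, 3.0),
        seed=seed,
        gene_ids=tuple(genes),
    )
    counts, truth = simulate_counts(spec)
    de = naive_de_table(counts, spec.n_samples_per_group)
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False, float_format="%.10g")
    truth.to_csv(outdir / "de_truth.tsv", sep="\t", index=False, float_format="%.10g")

    for i in range(3):
        net = simulate_network(
            RandomNetSpec(n_metabolites=6, n_reactions=10, seed=seed + 1 + i)
        )
        (outdir / f"network_{i+1}.tsv").write_text(serialize_reaction_table(net))

    names = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    for name in names:
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        files[name] = digest
    manifest = {"seed": seed, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
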