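"""Synthetic systems-genetics data with exported ground truth.

Emulates the structure of a cross-style eQTL dataset: a random gene
regulatory DAG, one biallelic cis-variant per gene, and expression generated
by linear-Gaussian structural equations over the DAG,

    X_i = alpha_i * E_i + sum_{p in parents(i)} beta_{p->i} * X_p + eps_i,

with eps_i ~ Normal(0, sigma_i^2).  Genotypes are independent
Bernoulli(maf) draws per variant (haploid) or Binomial(2, maf) (diploid);
no linkage disequilibrium, epistasis or hidden confounding is simulated.

Default effect scales — cis effects uniform on +/-[0.5, 1.5], trans effects
uniform on +/-[0.3, 1.0], unit noise, minor-allele frequencies uniform on
[0.1, 0.5] — put the cis-only R^2 of a typical root gene near 0.1 while
leaving clear headroom for network-based prediction gains.

Everything is deterministic given one master seed, which is expanded into
independent per-stage substreams (DAG, effect sizes, genotypes, noise), so
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .data import EqtlCatalog, ExpressionMatrix, GenotypeMatrix
from .network import Grn

__all__ = [
    "SimulationTruth",
    "simulate_dag",
    "make_truth",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
    "write_truth",
    "read_truth",
]

_STAGES = ("dag", "effects", "genotypes", "noise")


def _substream(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Generative ground truth: DAG, effect sizes, noise scales, MAFs."""

    dag: Grn
    cis_effects: Mapping[str, float]          # gene -> alpha
    trans_effects: Mapping[tuple[str, str], float]  # (parent, child) -> beta
    noise_sd: Mapping[str, float]             # gene -> sigma (>= 0)
    maf: Mapping[str, float]                  # variant -> allele frequency
    gene_variant: Mapping[str, str]           # gene -> its cis variant
    ploidy: int
    seed: int

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")
        if any(not 0 < f <= 0.5 for f in self.maf.values()):
            raise ValueError("maf values must lie in (0, 0.5]")

    @property
    def gene_ids(self) -> list[str]:
        return self.dag.nodes

    @property
    def variant_ids(self) -> list[str]:
        return [self.gene_variant[g] for g in self.gene_ids]

    def catalog(self) -> EqtlCatalog:
        return EqtlCatalog(
            {g: (self.gene_variant[g],) for g in self.gene_ids}
        )


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dag(n_genes: int, expected_parents: float, seed: int,
                 gene_ids: list[str] | None = None) -> Grn:
    """Random DAG with the given expected in-degree.

    A uniform node order is drawn; for each pair with i before j the edge
    i -> j is included independently with probability
    ``min(1, 2 * expected_parents / (n_genes - 1))``.  Each node has on
    average (n-1)/2 potential parents, so the mean in-degree is
    ``expected_parents``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if expected_parents < 0:
        raise ValueError("expected_parents must be >= 0")
    genes = gene_ids if gene_ids is not None else _gene_names(n_genes)
    rng = np.random.default_rng(seed)
    order = [genes[i] for i in rng.permutation(n_genes)]
    if n_genes == 1:
        return Grn(genes)
    p = min(1.0, 2.0 * expected_parents / (n_genes - 1))
    edges = []
    for i in range(n_genes):
        draws = rng.random(n_genes - i - 1) < p
        for k, hit in enumerate(draws):
            if hit:
                edges.append((order[i], order[i + 1 + k], 1.0))
    return Grn(genes, edges)


def make_truth(
    n_genes: int,
    expected_parents: float = 1.5,
    seed: int = 0,
    alpha_range: tuple[float, float] = (0.5, 1.5),
    beta_range: tuple[float, float] = (0.3, 1.0),
    noise_sd: float = 1.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    ploidy: int = 1,
    dag: Grn | None = None,
    alpha_scale: float = 1.0,
    beta_scale: float = 1.0,
) -> SimulationTruth:
    """Draw a complete generative ground truth.

    Cis effects are uniform on ``+/-alpha_range`` scaled by ``alpha_scale``
    and trans effects uniform on ``+/-beta_range`` scaled by ``beta_scale``
    (set a scale to 0 for null simulations).  ``dag`` overrides the random
    DAG, e.g. to simulate over an edgeless or hand-built network.
    """
    if dag is None:
        dag = simulate_dag(n_genes, expected_parents,
                           seed=_substream(seed, "dag").integers(2**31))
    genes = dag.nodes
    rng = _substream(seed, "effects")
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    mags = rng.uniform(*alpha_range, size=len(genes))
    cis = {g: alpha_scale * s * m for g, s, m in zip(genes, signs, mags)}
    edge_list = [(s, t) for s, t, _ in dag.edges]
    bsigns = rng.choice([-1.0, 1.0], size=len(edge_list))
    bmags = rng.uniform(*beta_range, size=len(edge_list))
    trans = {
        e: beta_scale * s * m for e, s, m in zip(edge_list, bsigns, bmags)
    }
    mafs = rng.uniform(*maf_range, size=len(genes))
    gene_variant = {g: f"v_{g}" for g in genes}
    return SimulationTruth(
        dag=dag,
        cis_effects=cis,
        trans_effects=trans,
        noise_sd={g: float(noise_sd) for g in genes},
        maf={gene_variant[g]: float(f) for g, f in zip(genes, mafs)},
        gene_variant=gene_variant,
        ploidy=ploidy,
        seed=seed,
    )


def simulate_genotypes(n_samples: int, truth: SimulationTruth) -> GenotypeMatrix:
    """Independent dosage draws per variant: Binomial(ploidy, maf)."""
    import pandas as pd

    rng = _substream(truth.seed, "genotypes")
    variants = truth.variant_ids
    mat = np.empty((n_samples, len(variants)), dtype=np.int64)
    for j, v in enumerate(variants):
        mat[:, j] = rng.binomial(truth.ploidy, truth.maf[v], size=n_samples)
    samples = [f"s{i:05d}" for i in range(1, n_samples + 1)]
    return GenotypeMatrix(
        pd.DataFrame(mat, index=samples, columns=variants), ploidy=truth.ploidy
    )


def simulate_expression(
    geno: GenotypeMatrix, truth: SimulationTruth,
    order: list[str] | None = None,
) -> ExpressionMatrix:
    """Generate expression by the structural equations, parents first.

    The noise matrix is drawn up front in a fixed gene order, so the output
    is independent of which valid topological order the traversal uses
    (``order`` lets a caller supply any valid one explicitly).
    """
    import pandas as pd

    genes = truth.gene_ids
    n = geno.n_samples
    col = {g: i for i, g in enumerate(genes)}
    rng = _substream(truth.seed, "noise")
    noise = rng.standard_normal((n, len(genes)))
    X = np.zeros((n, len(genes)))
    if order is None:
        order = truth.dag.topological_order()
    else:
        seen: set[str] = set()
        for g in order:
            if any(p not in seen for p in truth.dag.parents(g)):
                raise ValueError("order is not a topological order of the DAG")
            seen.add(g)
        if set(order) != set(genes):
            raise ValueError("order must cover every gene exactly once")
    for g in order:
        i = col[g]
        e = geno.column(truth.gene_variant[g]).astype(float)
        x = truth.cis_effects[g] * e + truth.noise_sd[g] * noise[:, i]
        for p in truth.dag.parents(g):
            x = x + truth.trans_effects[(p, g)] * X[:, col[p]]
        X[:, i] = x
    return ExpressionMatrix(
        pd.DataFrame(X, index=geno.sample_ids, columns=genes)
    )


def simulate_dataset(
    n_genes: int,
    n_samples: int,
    seed: int,
    **truth_kwargs,
) -> tuple[GenotypeMatrix, ExpressionMatrix, EqtlCatalog, SimulationTruth]:
    """One-call convenience: truth + genotypes + expression + catalog."""
    truth = make_truth(n_genes, seed=seed, **truth_kwargs)
    geno = simulate_genotypes(n_samples, truth)
    expr = simulate_expression(geno, truth)
    return geno, expr, truth.catalog(), truth


# ---------------------------------------------------------------------------
# Truth serialization (JSON; float repr round-trips exactly)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    doc = {
        "seed": truth.seed,
        "ploidy": truth.ploidy,
        "genes": truth.gene_ids,
        "gene_variant": dict(truth.gene_variant),
        "dag_edges": [[s, t] for s, t, _ in truth.dag.edges],
        "cis_effects": dict(truth.cis_effects),
        "trans_effects": {f"{p}\t{c}": b for (p, c), b in truth.trans_effects.items()},
        "noise_sd": dict(truth.noise_sd),
        "maf": dict(truth.maf),
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_truth(path: str | Path) -> SimulationTruth:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    dag = Grn(doc["genes"], [(s, t, 1.0) for s, t in doc["dag_edges"]])
    return SimulationTruth(
        dag=dag,
        cis_effects=doc["cis_effects"],
        trans_effects={
            tuple(k.split("\t")): v for k, v in doc["trans_effects"].items()
        },
        noise_sd=doc["noise_sd"],
        maf=doc["maf"],
        gene_variant=doc["gene_variant"],
        ploidy=doc["ploidy"],
        seed=doc["seed"],
    )
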