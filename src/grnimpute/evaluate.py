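"""Train/test evaluation of genetic-component prediction.

The protocol: split samples 80/20, fit every model on the training part
only (including expression scalers and CV folds), and report per-gene R^2
on the held-out part for the five input modes

- ``E``      cis-eQTLs only (the traditional baseline),
- ``E+Ep``   plus parent cis-eQTLs,
- ``E+Egp``  plus parent and grandparent cis-eQTLs,
- ``E+Xpp``  plus recursively predicted parent expression,
- ``E+Xp``   plus observed parent expression (upper benchmark; assumes
  parent expression is available, so it is not usable for imputation).

Summary means are taken over intermediate and leaf genes passing the
predictability criterion: test R^2 of at least 0.05 (inclusive) with the
combined E+Xp input.  The network-comparison helper instead averages over
all modelled genes so the gene set — and hence the network-independent E
column — is identical across networks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    DataValidationError,
    EqtlCatalog,
    ExpressionMatrix,
    GenotypeMatrix,
    PipelineConfig,
    SampleSplit,
)
from .imputation import CisModel, ImputationModelSet, fit_all
from .network import Grn, randomize_grn

__all__ = [
    "MODES",
    "EvalReport",
    "split_samples",
    "r2_score",
    "fit_mode_sets",
    "evaluate_models",
    "predictability_filter",
    "compare_networks",
]

#: evaluation input modes, and the trans stage each one uses
MODES = ("E", "E+Ep", "E+Egp", "E+Xpp", "E+Xp")
_TRANS_FOR_MODE = {"E": "E", "E+Ep": "Ep", "E+Egp": "Egp", "E+Xp": "Xp"}


def split_samples(
    sample_ids: Sequence[str], fraction: float = 0.8, seed: int = 0
) -> SampleSplit:
    """Uniform random train/test split without replacement."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(sample_ids)
    n = len(ids)
    n_train = int(round(n * fraction))
    if n_train == 0 or n_train == n:
        raise DataValidationError(
            f"cannot split {n} samples at fraction {fraction}: "
            "one side would be empty"
        )
    perm = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SampleSplit(train_ids=train, test_ids=test, seed=seed)


def r2_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    May be negative on test data.  NaN when the observed values have zero
    variance (the score is undefined there).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length vectors")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot


@dataclass(frozen=True)
class EvalReport:
    """Per-gene test R^2 per input mode, with the predictability flag.

    ``per_gene`` is indexed by gene id with columns ``node_class``, one R^2
    column per mode, and ``predictable``.  Summary means are recomputed from
    the table on demand, never cached.
    """

    per_gene: pd.DataFrame
    threshold: float

    def summary(self) -> pd.Series:
        """Mean R^2 per mode over predictable genes (NaN cells excluded)."""
        flagged = self.per_gene[self.per_gene["predictable"]]
        modes = [m for m in MODES if m in self.per_gene.columns]
        return pd.Series(
            {m: float(flagged[m].mean()) for m in modes}, name="mean_r2"
        )

    @property
    def n_predictable(self) -> int:
        return int(self.per_gene["predictable"].sum())

    def write(self, path: str | Path) -> None:
        self.per_gene.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path: str | Path, threshold: float = 0.05) -> "EvalReport":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(per_gene=df, threshold=threshold)


def fit_mode_sets(
    expr_train: ExpressionMatrix,
    geno_train: GenotypeMatrix,
    catalog: EqtlCatalog,
    grn: Grn,
    config: PipelineConfig,
    modes: Sequence[str] = MODES,
    cis_models: Mapping[str, CisModel] | None = None,
) -> dict[str, ImputationModelSet]:
    """Fit one model set per evaluation mode on the training samples.

    ``E+Xpp`` needs no fit of its own: it reuses the ``E+Xp`` models with
    recursively predicted parents at inference time.  The cis stage is
    fitted once and shared across modes.
    """
    sets: dict[str, ImputationModelSet] = {}
    wanted = [m for m in modes if m != "E+Xpp"]
    if "E+Xpp" in modes and "E+Xp" not in wanted:
        wanted.append("E+Xp")
    if cis_models is None:
        base = fit_all(expr_train, geno_train, catalog, grn, "E", config)
        cis_models = {g: m.cis for g, m in base.models.items()}
        if "E" in wanted:
            sets["E"] = base
    for mode in wanted:
        if mode in sets:
            continue
        sets[mode] = fit_all(
            expr_train, geno_train, catalog, grn, _TRANS_FOR_MODE[mode],
            config, cis_models=cis_models,
        )
    return sets


def evaluate_models(
    model_sets: Mapping[str, ImputationModelSet],
    geno_test: GenotypeMatrix,
    expr_test: ExpressionMatrix,
    threshold: float = 0.05,
    node_classes: tuple[str, ...] = ("intermediate", "leaf"),
) -> EvalReport:
    """Per-gene test R^2 for each available mode, with predictability flags.

    ``model_sets`` maps evaluation-mode names (``E``, ``E+Ep``, ``E+Egp``,
    ``E+Xp``) to fitted sets from the same training split; ``E+Xpp`` is
    derived from the ``E+Xp`` set by recursive prediction.  The report is
    restricted to the requested node classes of the network (pass all three
    classes to keep root genes too).
    """
    if not model_sets:
        raise ValueError("no model sets supplied")
    any_set = next(iter(model_sets.values()))
    grn = any_set.grn
    predictions: dict[str, ExpressionMatrix] = {}
    for mode, ms in model_sets.items():
        if mode == "E+Xp":
            predictions[mode] = ms.predict(geno_test, parent_expr_new=expr_test)
        else:
            predictions[mode] = ms.predict(geno_test)
    if "E+Xp" in model_sets:
        predictions["E+Xpp"] = model_sets["E+Xp"].predict(
            geno_test, recursive=True
        )
    genes = [
        g for g in any_set.gene_ids
        if (grn.node_class(g) if grn.has_node(g) else "root") in node_classes
    ]
    rows = []
    for g in genes:
        row: dict[str, object] = {
            "gene_id": g,
            "node_class": grn.node_class(g) if grn.has_node(g) else "root",
        }
        obs = expr_test.column(g)
        for mode in MODES:
            if mode in predictions and g in set(predictions[mode].gene_ids):
                row[mode] = r2_score(obs, predictions[mode].column(g))
            else:
                row[mode] = np.nan
        rows.append(row)
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "node_class", *MODES]
    ).set_index("gene_id")
    if "E+Xp" in predictions:
        per_gene["predictable"] = per_gene["E+Xp"] >= threshold
    else:
        per_gene["predictable"] = True
    return EvalReport(per_gene=per_gene, threshold=threshold)


def predictability_filter(report: EvalReport, threshold: float) -> EvalReport:
    """Recompute the predictable flag: R^2(E+Xp) >= threshold, inclusive."""
    if "E+Xp" not in report.per_gene.columns:
        raise ValueError("report lacks the E+Xp column")
    per_gene = report.per_gene.copy()
    per_gene["predictable"] = per_gene["E+Xp"] >= threshold
    return EvalReport(per_gene=per_gene, threshold=threshold)


def compare_networks(
    expr_train: ExpressionMatrix,
    geno_train: GenotypeMatrix,
    expr_test: ExpressionMatrix,
    geno_test: GenotypeMatrix,
    catalog: EqtlCatalog,
    networks: Mapping[str, Grn],
    config: PipelineConfig,
    modes: Sequence[str] = MODES,
    randomize: str | None = None,
    n_random: int | None = None,
) -> pd.DataFrame:
    """Mean test R^2 per (network, mode), long format.

    When ``randomize`` names one of the networks, ``n_random`` (default from
    the config) topology-preserving randomizations of it are evaluated and
    reported as a single averaged ``random`` entry, each replicate seeded
    from the config seed.

    Means are over all modelled genes — no node-class restriction or
    predictability filter — so every network is scored on the identical gene
    set and the cis-only ``E`` column is network-invariant by construction.
    The cis stage is fitted once and shared by every network.
    """
    base = fit_all(expr_train, geno_train, catalog, networks[next(iter(networks))]
                   if networks else Grn([]), "E", config)
    cis_models = {g: m.cis for g, m in base.models.items()}

    def one_network(grn: Grn) -> dict[str, float]:
        sets = fit_mode_sets(
            expr_train, geno_train, catalog, grn, config,
            modes=modes, cis_models=cis_models,
        )
        report = evaluate_models(
            sets, geno_test, expr_test,
            threshold=config.predictability_threshold,
            node_classes=("root", "intermediate", "leaf"),
        )
        cols = [m for m in MODES if m in modes]
        return {m: float(report.per_gene[m].mean()) for m in cols}

    rows = []
    for name, grn in networks.items():
        means = one_network(grn)
        for mode, value in means.items():
            rows.append({"network": name, "mode": mode, "mean_r2": value})
    if randomize is not None:
        n_rand = n_random if n_random is not None else config.n_random_networks
        acc: dict[str, list[float]] = {}
        for k in range(n_rand):
            rand = randomize_grn(networks[randomize], seed=config.seed + 1000 + k)
            for mode, value in one_network(rand).items():
                acc.setdefault(mode, []).append(value)
        for mode, values in acc.items():
            rows.append({
                "network": "random",
                "mode": mode,
                "mean_r2": float(np.mean(values)),
            })
    return pd.DataFrame(rows, columns=["network", "mode", "mean_r2"])
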