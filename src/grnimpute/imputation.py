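"""Per-gene prediction of the genetic component of expression.

The model is fitted in two stages, which also defines the cis/trans
decomposition.  For each gene g with cis-eQTL genotypes E_g:

1. cis stage — regress the expression X_g on E_g (training samples only,
   genotype features unstandardized) giving the cis prediction
   ``Xhat_cis = E_g @ alpha_hat``;
2. trans stage — regress the cis residual ``xi = X_g - Xhat_cis`` on a
   network-derived input: the top cis-eQTLs of g's parents (mode ``Ep``),
   of parents and grandparents (mode ``Egp``), or the parents' expression
   levels (mode ``Xp``, standardized with training-set mean/sd).

The predicted genetic component is the exact sum ``Xhat_cis + Xhat_trans``;
root genes (no parents) have no trans stage and their genetic component is
the cis prediction alone.  The recursive predictor reuses the Xp-fitted
trans models, substituting recursively predicted parent expression for
observed expression at inference time, roots first, in topological order.

:class:`GrnImputation` is the user-facing model object (data + network +
input mode); its :meth:`~GrnImputation.fit` returns a
:class:`GrnImputationResults` carrying the fitted per-gene models, the
training residuals and prediction/summary methods.  The module-level
functions implement the individual fitting steps.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
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
)
from .network import Grn
from .regression import make_regressor

__all__ = [
    "CisModel",
    "TransModel",
    "GeneModel",
    "ResidualMatrix",
    "ImputationModelSet",
    "GrnImputation",
    "GrnImputationResults",
    "TRANS_MODES",
    "fit_cis_model",
    "compute_residuals",
    "build_trans_input",
    "fit_trans_model",
    "predict_gene",
    "predict_recursive",
    "fit_all",
]

logger = logging.getLogger(__name__)

#: trans-input modes; "E" means cis-only (no trans stage)
TRANS_MODES = ("E", "Ep", "Egp", "Xp")


def gene_seed(master_seed: int, gene_id: str) -> int:
    """Stable per-gene sub-seed for CV fold assignment (< 2**31)."""
    return (zlib.crc32(gene_id.encode()) ^ (master_seed * 2654435761)) % (2**31)


@dataclass(frozen=True)
class CisModel:
    """Linear model of a gene's expression on its own cis-eQTL dosages."""

    gene_id: str
    variant_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    backend: str

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.variant_ids):
            raise ValueError("coefficient / variant count mismatch")

    def predict(self, geno: GenotypeMatrix) -> np.ndarray:
        if not self.variant_ids:
            return np.full(geno.n_samples, self.intercept)
        X = geno.data[list(self.variant_ids)].to_numpy(dtype=float)
        return X @ np.asarray(self.coefficients) + self.intercept


@dataclass(frozen=True)
class TransModel:
    """Linear model of a gene's cis residual on network-derived features.

    ``feature_ids`` are variant ids (modes Ep/Egp) or parent gene ids
    (mode Xp).  For Xp a per-feature (mean, sd) scaler fitted on the
    training samples is stored and applied to any input at prediction time.
    """

    gene_id: str
    input_mode: str
    feature_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    scaler: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_ids):
            raise ValueError("coefficient / feature count mismatch")
        if (self.scaler is not None) != (self.input_mode == "Xp"):
            raise ValueError("scaler must be present iff input_mode is 'Xp'")

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict from *raw* feature columns ordered as ``feature_ids``."""
        F = np.asarray(features, dtype=float)
        if self.scaler is not None:
            means = np.array([m for m, _ in self.scaler])
            sds = np.array([s for _, s in self.scaler])
            F = (F - means) / sds
        return F @ np.asarray(self.coefficients) + self.intercept


@dataclass(frozen=True)
class GeneModel:
    """cis model plus optional trans model; trans is absent for root genes."""

    cis: CisModel
    trans: TransModel | None = None


@dataclass(frozen=True)
class ResidualMatrix:
    """Training-sample residuals xi = X - Xhat_cis, samples x genes."""

    data: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    def column(self, gene_id: str) -> np.ndarray:
        return self.data[gene_id].to_numpy()


# ---------------------------------------------------------------------------
# fitting steps


def fit_cis_model(
    expr_train: ExpressionMatrix,
    geno_train: GenotypeMatrix,
    catalog: EqtlCatalog,
    gene_id: str,
    config: PipelineConfig,
) -> CisModel:
    """Fit the cis stage for one gene on training samples.

    Genotype features are left unstandardized.  If every cis variant is
    monomorphic in the training samples the model degenerates to the
    training mean (zero coefficients), with a logged warning.
    """
    variants = (
        catalog.variants(gene_id) if config.all_eqtls
        else (catalog.top_variant(gene_id),)
    )
    y = expr_train.column(gene_id)
    informative = [v for v in variants if not geno_train.is_monomorphic(v)]
    if not informative:
        logger.warning(
            "gene %s: all cis variants monomorphic in training data; "
            "cis model is the training mean", gene_id,
        )
        return CisModel(
            gene_id=gene_id,
            variant_ids=tuple(variants),
            coefficients=np.zeros(len(variants)),
            intercept=float(y.mean()),
            backend=config.backend,
        )
    X = geno_train.data[list(variants)].to_numpy(dtype=float)
    reg = make_regressor(config, random_state=gene_seed(config.seed, gene_id))
    reg.fit(X, y)
    return CisModel(
        gene_id=gene_id,
        variant_ids=tuple(variants),
        coefficients=np.asarray(reg.coef_, dtype=float),
        intercept=float(reg.intercept_),
        backend=config.backend,
    )


def compute_residuals(
    expr_train: ExpressionMatrix,
    geno_train: GenotypeMatrix,
    cis_models: Mapping[str, CisModel],
) -> ResidualMatrix:
    """xi_g = X_g - Xhat_cis_g on training samples, for every modelled gene."""
    cols = {}
    for gene_id, model in cis_models.items():
        if gene_id not in expr_train.data.columns:
            logger.warning("gene %s has a cis model but no expression; skipped",
                           gene_id)
            continue
        cols[gene_id] = expr_train.column(gene_id) - model.predict(geno_train)
    return ResidualMatrix(pd.DataFrame(cols, index=expr_train.sample_ids))


def build_trans_input(
    grn: Grn,
    gene_id: str,
    mode: str,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    catalog: EqtlCatalog,
    all_eqtls: bool = False,
) -> tuple[np.ndarray, tuple[str, ...]] | None:
    """Assemble the raw trans-stage design matrix for one gene.

    Returns None for root genes (no parents) or when no usable feature
    exists.  Modes:

    - ``Ep``: top cis-eQTLs of the parents, deduplicated;
    - ``Egp``: top cis-eQTLs of parents and grandparents, deduplicated;
    - ``Xp``: expression columns of the parents (unstandardized here; the
      trans fit standardizes with training statistics and stores them).
    """
    if mode not in ("Ep", "Egp", "Xp"):
        raise ValueError(f"unknown trans input mode {mode!r}")
    parents = grn.parents(gene_id) if grn.has_node(gene_id) else []
    if not parents:
        return None
    if mode == "Xp":
        present = [p for p in parents if p in set(expr.gene_ids)]
        if not present:
            return None
        F = expr.data[present].to_numpy(dtype=float)
        return F, tuple(present)
    sources = list(parents)
    if mode == "Egp":
        sources += [g for g in grn.grandparents(gene_id) if g not in set(parents)]
    feature_ids: list[str] = []
    for src in sources:
        if src not in catalog:
            logger.debug("parent %s of %s lacks a catalog eQTL; no column",
                         src, gene_id)
            continue
        variants = catalog.variants(src) if all_eqtls else (catalog.top_variant(src),)
        for v in variants:
            if v not in feature_ids:
                feature_ids.append(v)
    if not feature_ids:
        return None
    F = geno.data[feature_ids].to_numpy(dtype=float)
    return F, tuple(feature_ids)


def fit_trans_model(
    residual: np.ndarray,
    features: np.ndarray,
    feature_ids: Sequence[str],
    gene_id: str,
    mode: str,
    config: PipelineConfig,
) -> TransModel | None:
    """Fit the trans stage: residual ~ features.  None when featureless."""
    if features is None or features.shape[1] == 0:
        return None
    F = np.asarray(features, dtype=float)
    scaler = None
    if mode == "Xp":
        means = F.mean(axis=0)
        sds = F.std(axis=0)
        sds = np.where(sds > 0, sds, 1.0)  # constant parent stays centered
        scaler = tuple((float(m), float(s)) for m, s in zip(means, sds))
        F = (F - means) / sds
    reg = make_regressor(config, random_state=gene_seed(config.seed, gene_id))
    reg.fit(F, np.asarray(residual, dtype=float))
    return TransModel(
        gene_id=gene_id,
        input_mode=mode,
        feature_ids=tuple(feature_ids),
        coefficients=np.asarray(reg.coef_, dtype=float),
        intercept=float(reg.intercept_),
        scaler=scaler,
    )


def _trans_features_for_prediction(
    model: TransModel,
    geno_new: GenotypeMatrix,
    parent_expr_new: ExpressionMatrix | None,
) -> np.ndarray:
    if model.input_mode in ("Ep", "Egp"):
        return geno_new.data[list(model.feature_ids)].to_numpy(dtype=float)
    if parent_expr_new is None:
        raise DataValidationError(
            f"gene {model.gene_id}: mode Xp prediction requires parent "
            "expression"
        )
    missing = [g for g in model.feature_ids
               if g not in set(parent_expr_new.gene_ids)]
    if missing:
        raise DataValidationError(
            f"gene {model.gene_id}: parent expression missing for {missing}"
        )
    return parent_expr_new.data[list(model.feature_ids)].to_numpy(dtype=float)


def predict_gene(
    model: GeneModel,
    geno_new: GenotypeMatrix,
    parent_expr_new: ExpressionMatrix | None = None,
) -> np.ndarray:
    """Genetic-component prediction: exactly cis + trans (cis alone if root)."""
    pred = model.cis.predict(geno_new)
    if model.trans is not None:
        F = _trans_features_for_prediction(model.trans, geno_new, parent_expr_new)
        pred = pred + model.trans.predict(F)
    return pred


@dataclass(frozen=True)
class ImputationModelSet:
    """The fitted per-gene models over one network and input mode."""

    grn: Grn
    models: Mapping[str, GeneModel]
    config: PipelineConfig
    mode: str

    @property
    def gene_ids(self) -> list[str]:
        return list(self.models)

    def predict(
        self,
        geno_new: GenotypeMatrix,
        parent_expr_new: ExpressionMatrix | None = None,
        recursive: bool = False,
    ) -> ExpressionMatrix:
        if recursive:
            return predict_recursive(self, geno_new)
        cols = {
            g: predict_gene(m, geno_new, parent_expr_new)
            for g, m in self.models.items()
        }
        return ExpressionMatrix(pd.DataFrame(cols, index=geno_new.sample_ids))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def trans_doc(t: TransModel | None):
            if t is None:
                return None
            return {
                "input_mode": t.input_mode,
                "feature_ids": list(t.feature_ids),
                "coefficients": list(map(float, t.coefficients)),
                "intercept": t.intercept,
                "scaler": [list(p) for p in t.scaler] if t.scaler else None,
            }

        doc = {
            "mode": self.mode,
            "config": json.loads(self.config.to_json()),
            "grn": {
                "nodes": self.grn.nodes,
                "edges": [[s, t, p] for s, t, p in self.grn.edges],
            },
            "models": {
                g: {
                    "cis": {
                        "variant_ids": list(m.cis.variant_ids),
                        "coefficients": list(map(float, m.cis.coefficients)),
                        "intercept": m.cis.intercept,
                        "backend": m.cis.backend,
                    },
                    "trans": trans_doc(m.trans),
                }
                for g, m in self.models.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ImputationModelSet":
        doc = json.loads(text)
        cfg_doc = doc["config"]
        cfg = PipelineConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg_doc.items()
        })
        grn = Grn(doc["grn"]["nodes"],
                  [(s, t, p) for s, t, p in doc["grn"]["edges"]])
        models = {}
        for g, m in doc["models"].items():
            cis = CisModel(
                gene_id=g,
                variant_ids=tuple(m["cis"]["variant_ids"]),
                coefficients=np.asarray(m["cis"]["coefficients"]),
                intercept=m["cis"]["intercept"],
                backend=m["cis"]["backend"],
            )
            trans = None
            if m["trans"] is not None:
                t = m["trans"]
                trans = TransModel(
                    gene_id=g,
                    input_mode=t["input_mode"],
                    feature_ids=tuple(t["feature_ids"]),
                    coefficients=np.asarray(t["coefficients"]),
                    intercept=t["intercept"],
                    scaler=tuple(tuple(p) for p in t["scaler"])
                    if t["scaler"] else None,
                )
            models[g] = GeneModel(cis=cis, trans=trans)
        return cls(grn=grn, models=models, config=cfg, mode=doc["mode"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ImputationModelSet":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def predict_recursive(
    model_set: ImputationModelSet, geno_new: GenotypeMatrix
) -> ExpressionMatrix:
    """Recursive genetic-component prediction from genotypes alone.

    Requires Xp-mode trans models.  Genes are visited in topological order:
    roots get their cis prediction; each child's trans input is the already
    predicted expression of its parents, standardized with the stored
    training scalers.
    """
    if model_set.mode not in ("Xp", "E"):
        raise DataValidationError(
            "recursive prediction requires Xp-mode (or cis-only) models, "
            f"got mode {model_set.mode!r}"
        )
    preds: dict[str, np.ndarray] = {}
    for g in model_set.grn.topological_order():
        model = model_set.models.get(g)
        if model is None:
            continue
        pred = model.cis.predict(geno_new)
        if model.trans is not None:
            missing = [p for p in model.trans.feature_ids if p not in preds]
            if missing:
                raise DataValidationError(
                    f"gene {g}: parents {missing} not predicted before child"
                )
            F = np.column_stack([preds[p] for p in model.trans.feature_ids])
            pred = pred + model.trans.predict(F)
        preds[g] = pred
    # genes outside the network still have cis-only models
    for g, model in model_set.models.items():
        if g not in preds:
            preds[g] = model.cis.predict(geno_new)
    cols = {g: preds[g] for g in model_set.models}
    return ExpressionMatrix(pd.DataFrame(cols, index=geno_new.sample_ids))


def fit_all(
    expr_train: ExpressionMatrix,
    geno_train: GenotypeMatrix,
    catalog: EqtlCatalog,
    grn: Grn,
    mode: str,
    config: PipelineConfig,
    cis_models: Mapping[str, CisModel] | None = None,
) -> ImputationModelSet:
    """Fit cis models for every catalog gene and trans models per ``mode``.

    ``mode`` is one of ``E`` (cis only), ``Ep``, ``Egp`` or ``Xp``.
    Per-gene failures are logged and skipped; fitting fails only when no
    gene is fittable.  ``cis_models`` lets callers reuse an already fitted
    cis stage (it never depends on the network or the mode).
    """
    if mode not in TRANS_MODES:
        raise ValueError(f"mode must be one of {TRANS_MODES}, got {mode!r}")
    genes = [g for g in catalog.gene_ids if g in set(expr_train.gene_ids)]
    if not genes:
        raise DataValidationError("no catalog gene has expression data")
    if cis_models is None:
        cis_models = {}
        for g in genes:
            try:
                cis_models[g] = fit_cis_model(expr_train, geno_train, catalog,
                                              g, config)
            except Exception:  # pragma: no cover - defensive
                logger.exception("gene %s: cis fit failed; skipped", g)
    if not cis_models:
        raise DataValidationError("no gene could be fitted")
    models: dict[str, GeneModel] = {
        g: GeneModel(cis=m) for g, m in cis_models.items()
    }
    if mode != "E":
        residuals = compute_residuals(expr_train, geno_train, cis_models)
        for g in cis_models:
            built = build_trans_input(
                grn, g, mode, geno_train, expr_train, catalog,
                all_eqtls=config.all_eqtls,
            )
            if built is None:
                continue
            F, feature_ids = built
            trans = fit_trans_model(
                residuals.column(g), F, feature_ids, g, mode, config
            )
            if trans is not None:
                models[g] = GeneModel(cis=cis_models[g], trans=trans)
    return ImputationModelSet(grn=grn, models=models, config=config, mode=mode)


# ---------------------------------------------------------------------------
# model-object facade


class GrnImputation:
    """Genetic-component imputation model over a gene regulatory network.

    Parameters
    ----------
    expr, geno
        Aligned training expression and genotype matrices.
    catalog
        Gene -> cis-eQTL mapping; only catalog genes are modelled.
    grn
        The regulatory DAG used for the trans stage.
    mode
        Trans input: ``E`` (cis-only baseline), ``Ep``, ``Egp`` or ``Xp``.
    config
        Pipeline configuration (backend, grids, seed, ...).

    Examples
    --------
    >>> model = GrnImputation(expr, geno, catalog, grn, mode="Ep")
    >>> res = model.fit()
    >>> predictions = res.predict(geno_test)
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        geno: GenotypeMatrix,
        catalog: EqtlCatalog,
        grn: Grn,
        mode: str = "Ep",
        config: PipelineConfig | None = None,
    ):
        if expr.sample_ids != geno.sample_ids:
            raise DataValidationError(
                "expression and genotype samples are not aligned; "
                "call align_samples first"
            )
        catalog.validate_against(geno, expr)
        self.expr = expr
        self.geno = geno
        self.catalog = catalog
        self.grn = grn
        self.mode = mode
        self.config = config or PipelineConfig()

    def fit(self) -> "GrnImputationResults":
        model_set = fit_all(
            self.expr, self.geno, self.catalog, self.grn, self.mode,
            self.config,
        )
        return GrnImputationResults(self, model_set)


class GrnImputationResults:
    """Fitted results: per-gene models plus prediction and summary helpers."""

    def __init__(self, model: GrnImputation, model_set: ImputationModelSet):
        self.model = model
        self.model_set = model_set

    @property
    def models(self) -> Mapping[str, GeneModel]:
        return self.model_set.models

    def predict(
        self,
        geno_new: GenotypeMatrix,
        parent_expr_new: ExpressionMatrix | None = None,
        recursive: bool = False,
    ) -> ExpressionMatrix:
        return self.model_set.predict(geno_new, parent_expr_new, recursive)

    def fittedvalues(self) -> ExpressionMatrix:
        """In-sample genetic-component predictions (observed parents for Xp)."""
        return self.model_set.predict(self.model.geno, self.model.expr)

    def residuals(self) -> ResidualMatrix:
        cis = {g: m.cis for g, m in self.models.items()}
        return compute_residuals(self.model.expr, self.model.geno, cis)

    def summary(self) -> pd.DataFrame:
        """Per-gene table: node class, feature counts, training R^2."""
        from .evaluate import r2_score

        fitted = self.fittedvalues()
        rows = []
        for g, m in self.models.items():
            grn = self.model_set.grn
            rows.append({
                "gene_id": g,
                "node_class": grn.node_class(g) if grn.has_node(g) else "root",
                "backend": m.cis.backend,
                "n_cis_features": len(m.cis.variant_ids),
                "n_trans_features": 0 if m.trans is None
                else len(m.trans.feature_ids),
                "train_r2": r2_score(self.model.expr.column(g),
                                     fitted.column(g)),
            })
        return pd.DataFrame(rows).set_index("gene_id")

    def save(self, path: str | Path) -> None:
        self.model_set.save(path)
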