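"""End-to-end orchestration of the fused deep-feature framework.

Stages, for a labeled image collection and a set of feature extractors:

1. per extractor, build the 10*D fused deep-feature matrix (original image
   plus nine pooling-decomposition outputs);
2. per extractor, keep the top ``n_keep`` ReliefF-ranked features;
3. rank extractors by the cross-validated misclassification rate of a
   quadratic SVM on their selected features;
4. concatenate the selected blocks of the ``top_extractors`` lowest-loss
   extractors (ascending loss) into one fused matrix;
5. run iterative ReliefF on the fusion to pick the optimal subset length;
6. evaluate the final subset with the quadratic SVM under stratified k-fold
   cross-validation or a hold-out split, and report the full metric suite.

Column counts along the way are 10*D -> n_keep -> top*n_keep -> best_length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split

from .features import FeatureExtractor, LabeledFeatureMatrix, build_dataset
from .metrics import ClassificationReport, SVMSpec, compute_report, fit_predict_svm, make_svm
from .relieff import IRFResult, irf_select, rank_features, select_top

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    Defaults mirror the framework's reference configuration: keep 1000
    features per extractor, fuse the best 5 extractors, sweep IRF subset
    lengths over [100, 1000], and score everything with 10-fold stratified
    cross-validation.  ``validation="holdout"`` switches the final
    evaluation to a stratified train/test split of ``holdout_fraction``.
    On toy problems where matrices have fewer than ``n_keep`` columns the
    pipeline clamps ``n_keep`` and the IRF range to what exists.
    """

    n_keep: int = 1000
    top_extractors: int = 5
    irf_range: tuple = (100, 1000)
    folds: int = 10
    relieff_k: int = 10
    validation: str = "kfold"          # "kfold" | "holdout"
    holdout_fraction: float = 0.1
    fold_safe: bool = False
    seed: int = 0
    svm: SVMSpec = field(default_factory=SVMSpec)

    def __post_init__(self):
        if self.n_keep < 1 or self.top_extractors < 1 or self.folds < 2:
            raise ValueError("counts must be positive (folds >= 2)")
        lo, hi = self.irf_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid IRF range {self.irf_range}")
        if self.validation not in ("kfold", "holdout"):
            raise ValueError(f"unknown validation scheme {self.validation!r}")


@dataclass
class ExtractorLossTable:
    """Cross-validated misclassification rate per extractor, ascending."""

    losses: dict
    folds: int
    seed: int

    def ranked(self) -> list:
        """(name, loss) pairs sorted by ascending loss, ties by name."""
        return sorted(self.losses.items(), key=lambda kv: (kv[1], kv[0]))


@dataclass
class FusedFeatureSet:
    """Concatenation of the selected blocks of the best extractors."""

    data: LabeledFeatureMatrix
    chosen: list
    block_width: int


def classifier_loss(data: LabeledFeatureMatrix, folds: int = 10,
                    seed: int = 0, spec: SVMSpec = SVMSpec()) -> float:
    """Stratified k-fold CV misclassification rate of the quadratic SVM."""
    classes, counts = np.unique(data.y, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        raise ValueError(
            f"class(es) {list(small)} have fewer than {folds} members; "
            "cannot stratify"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(make_svm(spec), data.X, data.y, cv=cv)
    return float(np.mean(pred != data.y))


def rank_extractors(per_extractor: Mapping[str, LabeledFeatureMatrix],
                    folds: int = 10, seed: int = 0,
                    spec: SVMSpec = SVMSpec()) -> ExtractorLossTable:
    """Score every extractor's selected matrix by cross-validated SVM loss."""
    if not per_extractor:
        raise ValueError("no extractors to rank")
    ys = [m.y for m in per_extractor.values()]
    for other in ys[1:]:
        if not np.array_equal(ys[0], other):
            raise ValueError("all extractor matrices must share labels")
    losses = {
        name: classifier_loss(m, folds=folds, seed=seed, spec=spec)
        for name, m in per_extractor.items()
    }
    return ExtractorLossTable(losses=losses, folds=folds, seed=seed)


def fuse_top(per_extractor: Mapping[str, LabeledFeatureMatrix],
             table: ExtractorLossTable, top: int = 5) -> FusedFeatureSet:
    """Concatenate the ``top`` lowest-loss extractors' blocks, best first."""
    ranked = table.ranked()
    if top > len(ranked):
        raise ValueError(
            f"asked for top {top} of {len(ranked)} ranked extractors"
        )
    chosen = [name for name, _ in ranked[:top]]
    blocks = [per_extractor[name] for name in chosen]
    widths = {b.p for b in blocks}
    if len(widths) != 1:
        raise ValueError(f"selected blocks have unequal widths {widths}")
    rows = {b.n for b in blocks}
    if len(rows) != 1:
        raise ValueError("selected blocks have mismatched row counts")
    X = np.hstack([b.X for b in blocks])
    provenance = []
    for name, b in zip(chosen, blocks):
        if b.provenance:
            provenance.extend((name,) + tuple(pr[1:]) for pr in b.provenance)
        else:
            provenance.extend((name, None, j) for j in range(b.p))
    fused = LabeledFeatureMatrix(X=X, y=blocks[0].y, provenance=provenance)
    return FusedFeatureSet(data=fused, chosen=chosen, block_width=widths.pop())


@dataclass
class PipelineResult:
    """Artifacts of every stage of one full pipeline run."""

    per_extractor_full: dict
    per_extractor_selected: dict
    loss_table: ExtractorLossTable
    fused: FusedFeatureSet
    irf: IRFResult
    report: ClassificationReport
    stage_columns: dict


def _subset(data: LabeledFeatureMatrix, rows, cols=None) -> LabeledFeatureMatrix:
    X = data.X[rows]
    prov = data.provenance
    if cols is not None:
        X = X[:, cols]
        prov = [prov[j] for j in cols] if prov else []
    return LabeledFeatureMatrix(X, data.y[rows], prov)


def _fold_safe_split_predict(data: LabeledFeatureMatrix, tr, te,
                             n_select: int, config: PipelineConfig):
    """Rank features on the training rows only, then fit and predict."""
    ranking = rank_features(_subset(data, tr), k=config.relieff_k)
    cols = ranking.order[:n_select]
    return fit_predict_svm(_subset(data, tr, cols), _subset(data, te, cols),
                           config.svm)


def _final_report(data: LabeledFeatureMatrix, config: PipelineConfig,
                  fold_safe_length: Optional[int] = None) -> ClassificationReport:
    """Evaluate the final feature set.

    With ``fold_safe_length`` set, ``data`` is the pre-IRF fused matrix and
    the ReliefF ranking (top ``fold_safe_length`` columns) is recomputed
    inside each training split, so selection never sees evaluation rows.
    """
    if config.validation == "kfold":
        cv = StratifiedKFold(n_splits=config.folds, shuffle=True,
                             random_state=config.seed)
        if fold_safe_length is None:
            pred = cross_val_predict(make_svm(config.svm), data.X, data.y,
                                     cv=cv)
        else:
            pred = np.empty(data.n, dtype=data.y.dtype)
            for tr, te in cv.split(data.X, data.y):
                pred[te] = _fold_safe_split_predict(data, tr, te,
                                                    fold_safe_length, config)
        return compute_report(data.y, pred)
    idx = np.arange(data.n)
    tr, te = train_test_split(idx, test_size=config.holdout_fraction,
                              stratify=data.y, random_state=config.seed)
    if fold_safe_length is None:
        pred = fit_predict_svm(_subset(data, tr), _subset(data, te),
                               config.svm)
    else:
        pred = _fold_safe_split_predict(data, tr, te, fold_safe_length,
                                        config)
    return compute_report(data.y[te], pred)


def run_pipeline(images: Sequence, labels: Sequence,
                 extractors: Sequence[FeatureExtractor],
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full framework and return every stage's artifacts."""
    config = config or PipelineConfig()
    if len(extractors) < config.top_extractors:
        raise ValueError(
            f"need >= {config.top_extractors} extractors, got {len(extractors)}"
        )

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    full: dict = {}
    selected: dict = {}
    for ex in extractors:
        m = stage(f"features:{ex.name}",
                  lambda ex=ex: build_dataset(ex, images, labels))
        full[ex.name] = m
        n_keep = min(config.n_keep, m.p)
        ranking = stage(f"relieff:{ex.name}",
                        lambda m=m: rank_features(m, k=config.relieff_k))
        selected[ex.name] = select_top(m, ranking, n_keep)
        log.info("extractor %s: %d -> %d columns", ex.name, m.p, n_keep)

    table = stage("rank_extractors",
                  lambda: rank_extractors(selected, folds=config.folds,
                                          seed=config.seed, spec=config.svm))
    fused = stage("fuse_top",
                  lambda: fuse_top(selected, table, top=config.top_extractors))

    lo, hi = config.irf_range
    hi = min(hi, fused.data.p)
    lo = min(lo, hi)
    if (lo, hi) != tuple(config.irf_range):
        log.info("IRF range clamped to [%d, %d] for %d fused columns",
                 lo, hi, fused.data.p)

    def loss_fn(subset: LabeledFeatureMatrix) -> float:
        return classifier_loss(subset, folds=config.folds,
                               seed=config.seed, spec=config.svm)

    irf = stage("irf", lambda: irf_select(fused.data, loss_fn,
                                          range_lo=lo, range_hi=hi,
                                          k=config.relieff_k))
    if config.fold_safe:
        report = stage("classify", lambda: _final_report(
            fused.data, config, fold_safe_length=irf.best_length))
    else:
        final = select_top(fused.data, irf.ranking, irf.best_length)
        report = stage("classify", lambda: _final_report(final, config))

    stage_columns = {
        "per_extractor_full": {k: v.p for k, v in full.items()},
        "per_extractor_selected": {k: v.p for k, v in selected.items()},
        "fused": fused.data.p,
        "final": irf.best_length,
    }
    log.info("stage columns: %s", stage_columns)
    return PipelineResult(
        per_extractor_full=full,
        per_extractor_selected=selected,
        loss_table=table,
        fused=fused,
        irf=irf,
        report=report,
        stage_columns=stage_columns,
    )
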