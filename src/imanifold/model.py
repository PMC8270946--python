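"""Model and results objects for the intrinsic-manifold analysis.

:class:`BrainStateManifold` bundles one or more subjects' parcellated
time series with their stage labels and a :class:`PipelineConfig`;
``fit()`` runs the full pipeline — band-pass filter, Hilbert phase,
coherence states, CCD matrix, RMST graph, Laplacian-eigenmap embedding
(plus a PCA baseline), group alignment for multi-subject cohorts, and
linear-SVM decoding — and returns a :class:`ManifoldResults` carrying
every intermediate artefact, the decoding accuracies and, on request,
surrogate-based significance and ROC analyses.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import alignment as ga
from . import coherence as coh
from . import decoding as dec
from . import manifold as mf
from . import preprocessing as pre
from . import stats as st
from .config import PipelineConfig
from .datatypes import ManifoldEmbedding, ParcellatedTimeseries, StageLabels

logger = logging.getLogger(__name__)


@dataclass
class SubjectArtifacts:
    """Every per-subject intermediate of one pipeline run."""

    subject_id: str
    filtered: ParcellatedTimeseries
    phases: np.ndarray  # (N, T) wrapped radians
    ccd: np.ndarray  # (T, T)
    graph: mf.StateGraph
    embedding: ManifoldEmbedding  # Laplacian eigenmaps
    pca: ManifoldEmbedding  # PCA baseline on the filtered signal
    labels: StageLabels


def embed_subject(
    ts: ParcellatedTimeseries,
    labels: StageLabels,
    config: PipelineConfig,
    dim: int | None = None,
) -> SubjectArtifacts:
    """Run the per-subject stages: filter -> phase -> CCD -> RMST -> LE (+PCA)."""
    dim = dim or config.dim
    t0 = time.perf_counter()
    filtered = pre.bandpass(
        ts, config.band_low_hz, config.band_high_hz, config.filter_order
    )
    phases = pre.instantaneous_phase(filtered)
    if config.trim_trs > 0:
        k = config.trim_trs
        phases.phases = phases.phases[:, k:-k]
        filtered = ParcellatedTimeseries(
            filtered.data[:, k:-k], filtered.tr_seconds,
            list(filtered.region_ids), filtered.band,
        )
        labels = StageLabels(labels.labels[k:-k], labels.subject_id)
    if len(labels) != phases.n_trs:
        raise ValueError(
            f"{labels.subject_id}: {len(labels)} labels for {phases.n_trs} TRs"
        )
    ccd_m = coh.ccd_from_phases(phases)
    dist = mf.ccd_to_distance(ccd_m)
    graph = mf.rmst(
        dist, mf.RMSTParams(gamma=config.gamma, k_n=config.k_n, k_local=config.k_local)
    )
    L = mf.graph_laplacian(graph, weighting=config.laplacian_weighting)
    embedding = mf.laplacian_eigenmaps(L, dim)
    pca = mf.pca_embedding(filtered.data.T, min(dim, *filtered.data.shape))
    logger.info(
        "embedded %s: N=%d T=%d edges=%d d=%d (%.2fs)",
        labels.subject_id, filtered.n_regions, phases.n_trs,
        graph.n_edges, dim, time.perf_counter() - t0,
    )
    return SubjectArtifacts(
        subject_id=labels.subject_id,
        filtered=filtered,
        phases=phases.phases,
        ccd=ccd_m.matrix,
        graph=graph,
        embedding=embedding,
        pca=pca,
        labels=labels,
    )


class BrainStateManifold:
    """Intrinsic-manifold model of one or more subjects' brain dynamics.

    Parameters
    ----------
    timeseries : ParcellatedTimeseries or list thereof
    labels : StageLabels or list thereof (one per subject, same length as
        the corresponding series)
    config : PipelineConfig, optional

    Examples
    --------
    >>> model = BrainStateManifold(ts, labels, PipelineConfig(dim=7))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        timeseries: ParcellatedTimeseries | list[ParcellatedTimeseries],
        labels: StageLabels | list[StageLabels],
        config: PipelineConfig | None = None,
    ):
        if isinstance(timeseries, ParcellatedTimeseries):
            timeseries = [timeseries]
        if isinstance(labels, StageLabels):
            labels = [labels]
        if len(timeseries) != len(labels):
            raise ValueError("one label track per subject required")
        for ts, lab in zip(timeseries, labels):
            if ts.n_trs != len(lab):
                raise ValueError(
                    f"{lab.subject_id}: {len(lab)} labels for {ts.n_trs} TRs"
                )
        self.timeseries = timeseries
        self.labels = labels
        self.config = config or PipelineConfig()

    @property
    def n_subjects(self) -> int:
        return len(self.timeseries)

    @classmethod
    def from_files(
        cls,
        ts_paths: list[str],
        label_paths: list[str],
        tr_seconds: float,
        config: PipelineConfig | None = None,
    ) -> "BrainStateManifold":
        from . import io as mio

        ts_list, lab_list = [], []
        for k, (tp, lp) in enumerate(zip(ts_paths, label_paths)):
            ts = mio.read_timeseries(tp, tr_seconds)
            lab = mio.read_labels(lp, n_trs=ts.n_trs, subject_id=f"subject_{k}")
            ts_list.append(ts)
            lab_list.append(lab)
        return cls(ts_list, lab_list, config)

    def fit(
        self,
        run_surrogates: bool = False,
        n_perm: int | None = None,
        run_roc: bool = True,
    ) -> "ManifoldResults":
        """Execute the pipeline and collect results.

        ``run_surrogates=True`` additionally re-runs the full pipeline on
        ``n_perm`` (default ``config.n_perm``) phase-randomized surrogates
        of every subject to attach Monte-Carlo p-values to the multiclass
        decoding accuracies (FDR-corrected across subjects).
        """
        cfg = self.config
        subjects = [
            embed_subject(ts, lab, cfg)
            for ts, lab in zip(self.timeseries, self.labels)
        ]

        pairwise: dict[str, dict[tuple[str, str], dec.DecodingResult]] = {}
        multiclass: dict[str, dec.DecodingResult] = {}
        multiclass_pca: dict[str, dec.DecodingResult] = {}
        for art in subjects:
            stages = art.labels.stages
            pw = {}
            for a, b in itertools.combinations(stages, 2):
                pw[(a, b)] = dec.crossval_1v1(
                    art.embedding, art.labels, a, b,
                    n_folds=cfg.n_folds, seed=cfg.seed, C=cfg.svm_C,
                    fold_scheme=cfg.fold_scheme,
                )
            pairwise[art.subject_id] = pw
            multiclass[art.subject_id] = dec.crossval_1vall_multiclass(
                art.embedding, art.labels,
                n_folds=cfg.n_folds, seed=cfg.seed, C=cfg.svm_C,
                fold_scheme=cfg.fold_scheme,
            )
            multiclass_pca[art.subject_id] = dec.crossval_1vall_multiclass(
                art.pca, art.labels,
                n_folds=cfg.n_folds, seed=cfg.seed, C=cfg.svm_C,
                fold_scheme=cfg.fold_scheme,
            )

        aligned = None
        transforms = None
        loso = None
        if self.n_subjects > 1:
            aligned, transforms = ga.align_group(
                [a.embedding for a in subjects],
                [a.labels for a in subjects],
                reference_subject=cfg.reference_subject,
            )
            loso = dec.leave_one_subject_out(
                aligned, [a.labels for a in subjects], C=cfg.svm_C
            )

        roc = {}
        if run_roc:
            for art in subjects:
                stages = art.labels.stages
                for a, b in itertools.combinations(stages, 2):
                    roc[(art.subject_id, a, b)] = st.best_dimension_roc(
                        art.embedding, art.labels.labels, a, b,
                        dims_to_scan=min(cfg.roc_dims_to_scan, art.embedding.dim),
                    )

        significance = None
        if run_surrogates:
            significance = self._surrogate_significance(
                subjects, multiclass, n_perm or cfg.n_perm
            )

        return ManifoldResults(
            model=self,
            config=cfg,
            subjects=subjects,
            pairwise=pairwise,
            multiclass=multiclass,
            multiclass_pca=multiclass_pca,
            aligned=aligned,
            transforms=transforms,
            loso=loso,
            roc=roc,
            significance=significance,
        )

    def _surrogate_significance(
        self,
        subjects: list[SubjectArtifacts],
        multiclass: dict[str, dec.DecodingResult],
        n_perm: int,
    ) -> dict[str, st.SignificanceResult]:
        cfg = self.config
        out: dict[str, st.SignificanceResult] = {}
        for s, (ts, lab) in enumerate(zip(self.timeseries, self.labels)):
            ens = surrogate_null_accuracies(
                ts, lab, cfg, n_perm=n_perm, seed=cfg.seed + 7919 * (s + 1)
            )
            out[lab.subject_id] = st.significance_from_ensemble(
                multiclass[lab.subject_id].accuracy, ens
            )
        qvals, _ = st.fdr_correct(
            np.array([r.pvalue for r in out.values()]), alpha=cfg.fdr_alpha
        )
        for r, q in zip(out.values(), qvals):
            r.qvalue = float(q)
        return out


def surrogate_null_accuracies(
    ts: ParcellatedTimeseries,
    labels: StageLabels,
    config: PipelineConfig,
    n_perm: int,
    seed: int,
    mode: str = "full",
    decoder: str = "1vall",
    stage_pair: tuple[str, str] | None = None,
) -> np.ndarray:
    """Decoding accuracies on phase-randomized surrogates.

    ``mode="full"`` (the faithful default) re-runs the entire pipeline —
    filter, phase, CCD, RMST, Laplacian eigenmaps, SVM — on every
    surrogate series. ``mode="embedding_fixed"`` is a cheaper,
    NON-faithful shortcut that skips graph construction and embeds the
    surrogate CCD with PCA; it exists for quick checks only.
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for i in range(n_perm):
        surr = st.phase_randomized_surrogate(ts, rng)
        if mode == "full":
            art = embed_subject(surr, labels, config)
            emb, labels_i = art.embedding, art.labels
        elif mode == "embedding_fixed":
            filtered = pre.bandpass(
                surr, config.band_low_hz, config.band_high_hz, config.filter_order
            )
            phases = pre.instantaneous_phase(filtered)
            states = coh.coherence_states(phases)
            emb = mf.pca_embedding(states, config.dim)
            labels_i = labels
        else:
            raise ValueError(f"unknown surrogate mode {mode!r}")
        if decoder == "1vall":
            res = dec.crossval_1vall_multiclass(
                emb, labels_i, n_folds=config.n_folds, seed=config.seed,
                C=config.svm_C, fold_scheme=config.fold_scheme,
            )
        elif decoder == "1v1":
            if stage_pair is None:
                raise ValueError("1v1 decoder requires stage_pair")
            res = dec.crossval_1v1(
                emb, labels_i, *stage_pair, n_folds=config.n_folds,
                seed=config.seed, C=config.svm_C, fold_scheme=config.fold_scheme,
            )
        else:
            raise ValueError(f"unknown decoder {decoder!r}")
        accs[i] = res.accuracy
    return accs


@dataclass
class ManifoldResults:
    """Fitted pipeline results with a statsmodels-style ``summary()``."""

    model: BrainStateManifold
    config: PipelineConfig
    subjects: list[SubjectArtifacts]
    pairwise: dict[str, dict[tuple[str, str], dec.DecodingResult]]
    multiclass: dict[str, dec.DecodingResult]
    multiclass_pca: dict[str, dec.DecodingResult]
    aligned: list[ManifoldEmbedding] | None = None
    transforms: list[ga.AlignmentTransform] | None = None
    loso: dec.DecodingResult | None = None
    roc: dict = field(default_factory=dict)
    significance: dict[str, st.SignificanceResult] | None = None

    # -- aggregate accessors -------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return [a.subject_id for a in self.subjects]

    def mean_multiclass_accuracy(self, baseline: bool = False) -> float:
        source = self.multiclass_pca if baseline else self.multiclass
        return float(np.mean([r.accuracy for r in source.values()]))

    def mean_pairwise_accuracy(self) -> float:
        accs = [
            r.accuracy for pw in self.pairwise.values() for r in pw.values()
        ]
        return float(np.mean(accs))

    def pairwise_uncertainty(self, stage: str) -> float:
        """Eq.-style pooled uncertainty of one stage's pairwise accuracies:
        across-subject SDs of each comparison involving ``stage``, combined
        as (1/m) sqrt(sum e^2)."""
        comparisons: dict[tuple[str, str], list[float]] = {}
        for pw in self.pairwise.values():
            for pair, r in pw.items():
                if stage in pair:
                    comparisons.setdefault(pair, []).append(r.accuracy)
        if not comparisons:
            raise ValueError(f"no pairwise comparison involves {stage!r}")
        sds = [float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
               for v in comparisons.values()]
        return dec.combined_uncertainty(sds)

    def accuracy_by_dimension(
        self, dims: range | list[int], subject: int = 0
    ) -> dict[int, np.ndarray]:
        """Per-fold multiclass accuracies for nested embedding dimensions.

        Laplacian eigenvectors are nested (dimension d uses the first d
        non-trivial eigenvectors), so one eigen-solve at max(dims) serves
        the whole sweep.
        """
        dims = sorted(dims)
        art = self.subjects[subject]
        cfg = self.config
        max_d = max(dims)
        if art.embedding.dim >= max_d:
            full = art.embedding
        else:
            L = mf.graph_laplacian(art.graph, weighting=cfg.laplacian_weighting)
            full = mf.laplacian_eigenmaps(L, max_d)
        out: dict[int, np.ndarray] = {}
        for d in dims:
            sub = ManifoldEmbedding(
                coords=full.coords[:, :d],
                eigenvalues=full.eigenvalues[:d],
                method=full.method,
                ambient_dim=full.ambient_dim,
            )
            res = dec.crossval_1vall_multiclass(
                sub, art.labels, n_folds=cfg.n_folds, seed=cfg.seed,
                C=cfg.svm_C, fold_scheme=cfg.fold_scheme,
            )
            out[d] = res.per_fold
        return out

    def estimate_intrinsic_dimension(
        self, dims: range | list[int] | None = None, subject: int = 0
    ) -> mf.IntrinsicDimensionResult:
        """Plateau of the accuracy-vs-dimension curve (rank-sum + FDR)."""
        dims = list(dims) if dims is not None else list(range(1, 11))
        acc = self.accuracy_by_dimension(dims, subject=subject)
        return mf.estimate_intrinsic_dimension(acc, alpha=self.config.fdr_alpha)

    # -- reporting -----------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serialisable report of the whole run (no timestamps, so
        repeated seeded runs are hash-identical)."""
        report: dict = {
            "config": self.config.to_dict(),
            "n_subjects": len(self.subjects),
            "subjects": {},
        }
        for art in self.subjects:
            sid = art.subject_id
            entry = {
                "n_regions": art.filtered.n_regions,
                "n_trs": art.filtered.n_trs,
                "n_graph_edges": int(art.graph.n_edges),
                "n_mst_edges": int(len(art.graph.mst_edges)),
                "eigenvalues": art.embedding.eigenvalues.tolist(),
                "multiclass": self.multiclass[sid].to_dict(),
                "multiclass_pca": self.multiclass_pca[sid].to_dict(),
                "pairwise": {
                    f"{a}|{b}": r.to_dict()
                    for (a, b), r in self.pairwise[sid].items()
                },
            }
            if self.significance is not None:
                sig = self.significance[sid]
                entry["significance"] = {
                    "accuracy": sig.accuracy,
                    "pvalue": sig.pvalue,
                    "qvalue": sig.qvalue,
                    "n_perm": sig.n_perm,
                }
            report["subjects"][sid] = entry
        roc_entries = {}
        for (sid, a, b), r in self.roc.items():
            roc_entries[f"{sid}:{a}|{b}"] = {
                "auc": r.auc,
                "dimension_index": r.dimension_index,
                "flipped": r.flipped,
            }
        if roc_entries:
            report["roc"] = roc_entries
        if self.loso is not None:
            report["loso"] = self.loso.to_dict()
            report["alignment_residuals"] = [
                t.residual for t in (self.transforms or [])
            ]
        return report

    def summary(self) -> str:
        """Human-readable run summary."""
        cfg = self.config
        lines = [
            "Intrinsic manifold analysis",
            "=" * 60,
            f"subjects: {len(self.subjects)}   "
            f"embedding: laplacian_eigenmaps (d={cfg.dim})   "
            f"graph: RMST (gamma={cfg.gamma}, k_n={cfg.k_n})",
            f"band: {cfg.band_low_hz}-{cfg.band_high_hz} Hz "
            f"(Butterworth order {cfg.filter_order}, zero-phase)",
            "-" * 60,
        ]
        for art in self.subjects:
            sid = art.subject_id
            mc = self.multiclass[sid]
            pca = self.multiclass_pca[sid]
            lines.append(
                f"{sid}: multiclass accuracy {100 * mc.accuracy:.1f}% "
                f"(PCA baseline {100 * pca.accuracy:.1f}%), "
                f"graph edges {art.graph.n_edges}"
            )
            for (a, b), r in self.pairwise[sid].items():
                lines.append(f"    {a} vs {b}: {100 * r.accuracy:.1f}%")
            if self.significance is not None:
                sig = self.significance[sid]
                lines.append(
                    f"    surrogate null: p = {sig.pvalue:.4g} "
                    f"(q = {sig.qvalue:.4g}, {sig.n_perm} surrogates)"
                )
        if self.loso is not None:
            lines.append("-" * 60)
            lines.append(
                f"group LOSO accuracy: {100 * self.loso.accuracy:.1f}% "
                f"(per-round SD {100 * np.std(self.loso.per_fold):.1f}%)"
            )
        if self.roc:
            best = max(self.roc.values(), key=lambda r: r.auc)
            lines.append(
                f"best single-dimension AUC: {best.auc:.3f} "
                f"(dimension {best.dimension_index})"
            )
        return "\n".join(lines)
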