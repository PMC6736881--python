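"""End-to-end drivers tying the stages together.

``vlca_study`` goes from raw individual configurations to estimated
ancestral shapes: GPA, optional symmetric component and semilandmark
sliding, population mean shapes, PCA, Brownian-motion ancestral estimation
and back-rotation.  ``comparison_study`` runs the per-analysis restricted
GPA + bgPCA + distance tables with the vLCAs and fossil stand-ins as
passive specimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import (
    AnalysisSpec,
    BgPCAResult,
    bgpca,
    euclidean_distance_table,
    make_analysis_spec,
    nearest_groups,
    procrustes_distance_report,
)
from .geometry import (
    AlignedSample,
    LandmarkConfiguration,
    gpa,
    ordinary_procrustes,
    symmetric_component,
)
from .impute import impute_missing
from .phylo import Chronogram
from .scheme import LandmarkScheme
from .simulate import SyntheticDataset
from .sliding import slide_semilandmarks
from .vlca import ShapePCA, VirtualAncestor, ancestral_shapes, population_mean_shapes, shape_pca


@dataclass
class VlcaStudy:
    """Everything the ancestral-shape stage produces."""

    aligned: AlignedSample
    mean_shapes: dict[str, np.ndarray]
    pca: ShapePCA
    ancestors: dict[str, VirtualAncestor]
    tree: Chronogram


def vlca_study(
    individuals: list[LandmarkConfiguration],
    tree: Chronogram,
    scheme: LandmarkScheme | None = None,
    symmetrize: bool = True,
    slide_iterations: int = 0,
) -> VlcaStudy:
    """Estimate ancestral shapes from grouped individual configurations.

    Individuals must carry ``group`` labels matching the tree's tips.
    Symmetrization and sliding require a scheme; sliding defaults to off
    (synthetic data plants no spacing artefacts; enable for digitized data).
    """
    aligned = gpa(individuals)
    if slide_iterations > 0:
        if scheme is None:
            raise ValueError("sliding requires a landmark scheme")
        aligned = slide_semilandmarks(aligned, scheme, iterations=slide_iterations)
    if symmetrize:
        if scheme is None:
            raise ValueError("symmetrization requires a landmark scheme")
        aligned = symmetric_component(aligned, scheme)
    means = population_mean_shapes(aligned)
    order = [t for t in tree.tip_labels if t in means]
    if len(order) != tree.n_tips:
        missing = sorted(set(tree.tip_labels) - set(means))
        raise ValueError(f"tree tips without specimens: {missing}")
    pca = shape_pca({t: means[t] for t in order})
    ancestors = ancestral_shapes(tree, pca)
    return VlcaStudy(aligned, means, pca, ancestors, tree)


def root_recovery_error(study: VlcaStudy, true_root_shape: np.ndarray) -> dict[str, float]:
    """Compare the estimated root vLCA with the (known) true root shape.

    Both shapes are scaled to unit centroid size and superimposed by an
    ordinary Procrustes fit before differencing, so the error is a pure
    shape distance.  Returns the Procrustes distance, the per-landmark RMSE,
    and the tip dispersion (root-mean-square Procrustes distance of tip mean
    shapes to their grand mean) for scale.
    """
    root = study.ancestors[study.tree.root_id]
    est = root.unit_landmarks
    _, dist = ordinary_procrustes(est, np.asarray(true_root_shape, float))
    k = est.shape[0]

    means = np.stack(list(study.mean_shapes.values()))
    grand = means.mean(axis=0)
    disp = float(np.sqrt(np.mean([np.sum((m - grand) ** 2) for m in means])))
    return {
        "procrustes_distance": dist,
        "rmse_per_landmark": dist / np.sqrt(k),
        "tip_dispersion": disp,
        "tip_dispersion_rmse_per_landmark": disp / np.sqrt(k),
    }


@dataclass
class ComparisonAnalysis:
    """Outputs of one restricted analysis (A-D)."""

    spec: AnalysisSpec
    aligned: AlignedSample
    bg: BgPCAResult
    distance_table: object  # DataFrame
    nearest: object  # DataFrame
    boxplot_summary: object  # DataFrame


def comparison_study(
    ds: SyntheticDataset,
    study: VlcaStudy,
    analyses: tuple[str, ...] = ("A", "B", "C", "D"),
    exclude_groups: tuple[str, ...] = ("Hhabilis", "Hergaster", "Hgeorgicus"),
) -> dict[str, ComparisonAnalysis]:
    """Run the restricted analyses with vLCAs and fossils as passive specimens.

    Fossil stand-ins are imputed against the full-sample consensus, then for
    each analysis the individuals (early Homo excluded), the vLCAs and the
    fossils are restricted to the analysis landmark subset and re-aligned by
    a fresh GPA; bgPCA groups the individuals by population and projects the
    passive specimens.
    """
    template = LandmarkConfiguration("consensus", study.aligned.consensus)
    fossils = [impute_missing(f, template, ds.scheme) for f in ds.fossils]
    vlca_cfgs = [
        LandmarkConfiguration(f"vLCA_{nid}", anc.unit_landmarks)
        for nid, anc in study.ancestors.items()
        if nid == study.tree.root_id
        or nid == study.tree.mrca("EarlyHsapiens", "NorthAfrica")
    ]
    individuals = [c for c in ds.individuals if c.group not in exclude_groups]

    out: dict[str, ComparisonAnalysis] = {}
    for name in analyses:
        spec = make_analysis_spec(name, ds.scheme)
        idx = spec.landmark_indices
        cfgs: list[LandmarkConfiguration] = []
        passive_ids: list[str] = []
        for c in individuals:
            cfgs.append(LandmarkConfiguration(c.specimen_id, c.coords[idx], group=c.group))
        for c in vlca_cfgs + fossils:
            if c.specimen_id in spec.excluded_specimens:
                continue
            cfgs.append(LandmarkConfiguration(c.specimen_id, c.coords[idx]))
            passive_ids.append(c.specimen_id)
        aligned = gpa(cfgs)
        grouped = [c for c in aligned.configs if c.group is not None]
        passive = [c for c in aligned.configs if c.specimen_id in passive_ids]
        bg = bgpca(
            np.stack([c.coords for c in grouped]),
            [c.group for c in grouped],
            passive=np.stack([c.coords for c in passive]),
            passive_labels=[c.specimen_id for c in passive],
            individual_labels=[c.specimen_id for c in grouped],
        )
        table = euclidean_distance_table(bg)
        near = nearest_groups(bg)
        box = procrustes_distance_report(aligned, passive_ids)
        out[name] = ComparisonAnalysis(spec, aligned, bg, table, near, box)
    return out
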