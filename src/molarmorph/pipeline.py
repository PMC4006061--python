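"""End-to-end analysis pipeline.

Runs the full crown-form workflow on a landmark study (loaded from files
or simulated from a :class:`~molarmorph.synthetic_data.GeneratorSpec`):
measurement-error ANOVA, GPA, tangent PCA with dimensionality selection,
size descriptives and ANOVA, split-sex pairwise permutation tests for
size and shape, MANOVA/MANCOVA, allometric regression, size correction,
discriminant analysis, mean-shape PCA and TPS warps. Every table is a
DataFrame serializable to CSV; a manifest guarantees completeness and a
re-run with the same config and seed reproduces the report bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .errors import MolarmorphError
from .landmark_io import GROUPS, SEXES, read_classifiers, read_landmarks
from .procrustes import gpa
from .shape_space import (
    distance_correlation_profile,
    group_mean_shapes,
    mean_shape_pca,
    select_dimensionality,
    shape_pca,
    tps_warp,
)
from .group_stats import (
    allometry_regression,
    lda_crossval,
    mancova,
    manova,
    pairwise_permutation_tests,
    size_correct,
    two_way_anova,
)
from .error_anova import procrustes_anova
from .synthetic_data import GeneratorSpec, default_study_spec, generate_error_study, generate_study

#: every table a complete report must contain
EXPECTED_TABLES = (
    "error_anova_shape",
    "error_anova_size",
    "size_descriptives",
    "size_anova_interaction",
    "size_anova_main",
    "size_pairwise_F",
    "size_pairwise_M",
    "pca_summary",
    "shape_manova_interaction",
    "shape_manova_main",
    "shape_pairwise_F",
    "shape_pairwise_M",
    "mean_shape_pca_F",
    "mean_shape_pca_M",
    "allometry",
    "shape_mancova_interaction",
    "shape_mancova_main",
    "shape_pairwise_corrected_F",
    "shape_pairwise_corrected_M",
    "discriminant",
    "tps_bending_energy",
)


class PipelineError(MolarmorphError):
    """A pipeline stage failed; carries the stage name and a remedy hint."""

    def __init__(self, stage: str, exc: Exception, hint: str = ""):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {exc}" + (f" (hint: {hint})" if hint else ""))


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    Either file inputs (``landmarks`` + ``classifiers``) or a generator
    spec; when both are None the default synthetic study design is used.
    """

    landmarks: str | None = None
    classifiers: str | None = None
    dialect: str = "csv_long"
    generator: GeneratorSpec | None = None
    pcs: int | str = "auto"
    n_perm: int = 10000
    seed: int = 1
    split_sex: bool = True
    alpha: float = 0.05
    output_dir: str | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if self.pcs != "auto" and (not isinstance(self.pcs, int) or self.pcs < 1):
            raise ValueError("pcs must be 'auto' or a positive integer")


@dataclass
class AnalysisReport:
    """All tables, figure paths and run metadata of one pipeline run."""

    tables: dict[str, pd.DataFrame]
    figures: dict[str, str]
    metadata: dict

    def check_complete(self) -> None:
        missing = [t for t in EXPECTED_TABLES if t not in self.tables]
        if missing:
            raise PipelineError(
                "manifest", RuntimeError(f"missing tables: {missing}"), "report incomplete"
            )

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv")
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2, sort_keys=True))


def _effects_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results]).set_index("Effect")


def _stage(name: str, fn, hint: str = ""):
    try:
        return fn()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(name, exc, hint) from exc


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run the complete analysis workflow and return the report."""
    tables: dict[str, pd.DataFrame] = {}
    figures: dict[str, str] = {}

    spec = config.generator or default_study_spec(seed=config.seed)

    def load_data():
        if config.landmarks:
            ds = read_landmarks(config.landmarks, config.dialect)
            if config.classifiers:
                ds = ds.attach_records(read_classifiers(config.classifiers))
            return ds
        return generate_study(spec, seed=config.seed)

    dataset = _stage("load_data", load_data, "check input paths/dialect or generator spec")

    def error_stage():
        err = generate_error_study(spec, seed=config.seed + 1)
        tables["error_anova_shape"] = procrustes_anova(err, "shape").to_frame().set_index("Effect")
        tables["error_anova_size"] = procrustes_anova(err, "size").to_frame().set_index("Effect")

    _stage("error_anova", error_stage, "error study needs >= 2 scans and digitizations")

    fit = _stage("gpa", lambda: gpa(dataset), "need >= 2 non-degenerate configurations")
    groups = dataset.labels("group")
    sexes = dataset.labels("sex")
    cs = fit.centroid_sizes

    def descriptives():
        rows = []
        for s in SEXES:
            for g in GROUPS:
                sel = cs[(groups == g) & (sexes == s)]
                if len(sel) == 0:
                    continue
                rows.append(
                    {
                        "Sex": s,
                        "Group": g,
                        "Mean (mm)": sel.mean(),
                        "SD": sel.std(ddof=1) if len(sel) > 1 else 0.0,
                        "CV (%)": 100 * sel.std(ddof=1) / sel.mean() if len(sel) > 1 else 0.0,
                        "N": len(sel),
                    }
                )
        tables["size_descriptives"] = pd.DataFrame(rows).set_index(["Sex", "Group"])

    _stage("size_descriptives", descriptives)

    def size_anova():
        tables["size_anova_interaction"] = two_way_anova(cs, groups, sexes, True).table
        tables["size_anova_main"] = two_way_anova(cs, groups, sexes, False).table

    _stage("size_anova", size_anova, "every group x sex cell must be non-empty")

    def size_pairwise():
        for i, s in enumerate(SEXES):
            sel = sexes == s
            tables[f"size_pairwise_{s}"] = pairwise_permutation_tests(
                cs[sel],
                groups[sel],
                "mean_difference",
                n_perm=config.n_perm,
                seed=config.seed + 10 + i,
                alpha=config.alpha,
            ).to_frame()

    _stage("size_pairwise", size_pairwise, "each group needs >= 2 specimens per sex")

    def pca_stage():
        space = shape_pca(fit)
        profile = distance_correlation_profile(fit, space)
        if config.pcs == "auto":
            m, plateau = select_dimensionality(profile)
        else:
            m, plateau = int(config.pcs), int(config.pcs)
        # keep multivariate tests well-posed in small samples
        min_sex_n = min(int(np.sum(sexes == s)) for s in SEXES)
        m = max(1, min(m, space.n_nonzero, min_sex_n - 6))
        tables["pca_summary"] = pd.DataFrame(
            {
                "eigenvalue": space.eigenvalues,
                "percent_variance": space.percent_variance,
                "cumulative_percent": np.cumsum(space.percent_variance),
                "distance_correlation_r": profile.r_values[: space.n_components],
            },
            index=pd.RangeIndex(1, space.n_components + 1, name="PC"),
        )
        return space, profile, m, plateau

    space, profile, n_pcs, plateau = _stage("shape_pca", pca_stage, "need >= 3 specimens")
    scores = space.scores[:, :n_pcs]

    def manova_stage():
        tables["shape_manova_interaction"] = _effects_frame(
            manova(scores, groups, sexes, include_interaction=True)
        )
        tables["shape_manova_main"] = _effects_frame(
            manova(scores, groups, sexes, include_interaction=False)
        )

    _stage("shape_manova", manova_stage, "reduce pcs if the error matrix is singular")

    def shape_pairwise():
        for i, s in enumerate(SEXES):
            sel = sexes == s
            sub_fit = _subset_fit(fit, sel)
            tables[f"shape_pairwise_{s}"] = pairwise_permutation_tests(
                sub_fit,
                groups[sel],
                "procrustes_distance",
                n_perm=config.n_perm,
                seed=config.seed + 20 + i,
                alpha=config.alpha,
            ).to_frame()

    _stage("shape_pairwise", shape_pairwise)

    mean_shapes_by_sex = {}

    def mean_shape_stage():
        for s in SEXES:
            sel = sexes == s
            means = group_mean_shapes(_subset_fit(fit, sel), groups[sel], groups=list(GROUPS))
            mean_shapes_by_sex[s] = means
            msp = mean_shape_pca(means)
            tables[f"mean_shape_pca_{s}"] = pd.DataFrame(
                msp.scores[:, : min(3, msp.n_components)],
                index=pd.Index(list(means), name="Group"),
                columns=[f"PC{i + 1}" for i in range(min(3, msp.n_components))],
            )

    _stage("mean_shape_pca", mean_shape_stage)

    def tps_stage():
        rows = []
        for s in SEXES:
            means = mean_shapes_by_sex[s]
            ref = means["control"]
            for g in GROUPS[1:]:
                warp = tps_warp(ref, means[g])
                rows.append({"Sex": s, "Target": g, "BendingEnergy": warp.bending_energy})
        tables["tps_bending_energy"] = pd.DataFrame(rows).set_index(["Sex", "Target"])

    _stage("tps_warp", tps_stage, "mean shapes must be non-coplanar")

    def allometry_stage():
        rows = []
        for s in SEXES:
            for g in GROUPS:
                sel = (sexes == s) & (groups == g)
                if np.sum(sel) < 4:
                    continue
                res = allometry_regression(
                    fit.tangent_coords[sel],
                    cs[sel],
                    n_perm=config.n_perm,
                    seed=config.seed + 30,
                )
                rows.append(
                    {
                        "Sex": s,
                        "Group": g,
                        "%": res.percent_predicted,
                        "P-value": res.p_permutation,
                    }
                )
        tables["allometry"] = pd.DataFrame(rows).set_index(["Sex", "Group"])

    _stage("allometry", allometry_stage, "each cell needs >= 4 specimens and varying CS")

    def mancova_stage():
        frames_int, frames_main = [], []
        for s in SEXES:
            sel = sexes == s
            for include, acc in ((True, frames_int), (False, frames_main)):
                res = mancova(scores[sel], groups[sel], cs[sel], include_interaction=include)
                df = _effects_frame(res)
                df.insert(0, "Sex", s)
                acc.append(df)
        tables["shape_mancova_interaction"] = pd.concat(frames_int)
        tables["shape_mancova_main"] = pd.concat(frames_main)

    _stage("shape_mancova", mancova_stage, "reduce pcs if the error matrix is singular")

    corrected_scores_by_sex = {}

    def size_correct_stage():
        for i, s in enumerate(SEXES):
            sel = sexes == s
            corrected = size_correct(fit.tangent_coords[sel], cs[sel], groups[sel])
            sub_space = shape_pca(corrected)
            m = min(n_pcs, sub_space.n_nonzero)
            corrected_scores_by_sex[s] = sub_space.scores[:, :m]
            sub_fit = _subset_fit(fit, sel)
            sub_fit = _with_tangent(sub_fit, corrected)
            tables[f"shape_pairwise_corrected_{s}"] = pairwise_permutation_tests(
                sub_fit,
                groups[sel],
                "procrustes_distance",
                n_perm=config.n_perm,
                seed=config.seed + 40 + i,
                alpha=config.alpha,
            ).to_frame()

    _stage("size_correct", size_correct_stage)

    def da_stage():
        rows = []
        for s in SEXES:
            sel = sexes == s
            sc = corrected_scores_by_sex[s]
            n_s = sc.shape[0]
            p_da = min(sc.shape[1], n_s - len(GROUPS) - 1)
            res = lda_crossval(sc[:, :p_da], groups[sel])
            rows.append(
                {
                    "Sex": s,
                    "Wilks' Lambda": res.wilks.wilks_lambda,
                    "F": res.wilks.f,
                    "df1": res.wilks.df1,
                    "df2": res.wilks.df2,
                    "P": res.wilks.p,
                    "Accuracy": res.accuracy_resub,
                    "LOO Accuracy": res.accuracy_loo,
                }
            )
        tables["discriminant"] = pd.DataFrame(rows).set_index("Sex")

    _stage("discriminant", da_stage, "use fewer PCs if pooled covariance is singular")

    if config.make_figures and config.output_dir:
        _stage(
            "figures",
            lambda: _make_figures(
                config, figures, fit, space, profile, scores, groups, sexes, cs,
                mean_shapes_by_sex,
            ),
        )

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "pcs_requested": config.pcs,
        "pcs_used": int(n_pcs),
        "pcs_plateau": int(plateau),
        "split_sex": config.split_sex,
        "n_specimens": len(dataset),
        "gpa_iterations": fit.iterations,
        "gpa_converged": fit.converged,
    }
    report = AnalysisReport(tables=tables, figures=figures, metadata=metadata)
    report.check_complete()
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _subset_fit(fit, mask):
    from .procrustes import ProcrustesFit

    ids = None
    if fit.specimen_ids is not None:
        ids = [sid for sid, m in zip(fit.specimen_ids, mask) if m]
    return ProcrustesFit(
        aligned=fit.aligned[mask],
        consensus=fit.consensus,
        centroid_sizes=fit.centroid_sizes[mask],
        tangent_coords=fit.tangent_coords[mask],
        iterations=fit.iterations,
        converged=fit.converged,
        specimen_ids=ids,
    )


def _with_tangent(fit, tangent):
    fit.tangent_coords = tangent
    return fit


def _make_figures(config, figures, fit, space, profile, scores, groups, sexes, cs,
                  mean_shapes_by_sex) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def save(fig, name):
        path = out / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures[name] = str(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(1, len(profile.r_values) + 1), profile.r_values, marker="o", ms=3)
    ax.axhline(0.98, ls="--", c="gray")
    ax.set_xlabel("Number of PCs")
    ax.set_ylabel("r (reduced vs full shape distances)")
    save(fig, "distance_correlation")

    for s in SEXES:
        sel = sexes == s
        fig, ax = plt.subplots(figsize=(5, 4))
        for g in GROUPS:
            gsel = sel & (groups == g)
            ax.scatter(scores[gsel, 0], scores[gsel, 1], s=12, label=g)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        ax.set_title(f"Shape PC scores, sex {s}")
        save(fig, f"pc_scatter_{s}")

        means = mean_shapes_by_sex[s]
        warp = tps_warp(means["control"], means["severe"])
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
        for ax_i, (plane, data) in zip(axes, warp.grid.items()):
            pts = data["warped"]
            keep = [i for i in range(3) if plane[0] in "xyz"[i] or plane[1] in "xyz"[i]]
            ax_i.plot(pts[:, keep[0]], pts[:, keep[1]], ".", ms=1)
            ax_i.set_title(f"plane {plane}")
        fig.suptitle(f"TPS warp control -> severe, sex {s}", fontsize=9)
        save(fig, f"tps_grid_{s}")

    fig, ax = plt.subplots(figsize=(5, 4))
    data = [cs[(sexes == s) & (groups == g)] for s in SEXES for g in GROUPS]
    ax.boxplot(data, labels=[f"{s}:{g[:3]}" for s in SEXES for g in GROUPS])
    ax.set_ylabel("Centroid size (mm)")
    plt.setp(ax.get_xticklabels(), rotation=45, fontsize=7)
    save(fig, "size_boxplot")
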