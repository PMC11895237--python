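"""End-to-end orchestration of the cranial-morphology analysis.

Stages: obtain data (simulate or load) -> mirror + superimpose -> species
means -> PCA morphospace -> phylogenetic comparative fits (size ~ diet,
shape ~ diet x size, shape ~ size, dispersion, allometry, Pagel's lambda)
-> per-biome disparity with the richness-conditioned Monte Carlo null.
Each stage writes plain-text artifacts into the run directory and records
itself in a JSON manifest; a fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .datasets import TROPICAL_BIOMES, TEMPERATE_BIOMES
from .disparity import (
    TEMPERATE_HYPOTHESIS,
    TROPICAL_HYPOTHESIS,
    biome_disparity,
    biome_null_test,
    disparity_anova,
    richness_null,
    richness_regression,
)
from .morphospace import pca
from .pgls import allometry_scores, pairwise_dispersion, pgls_fit, parse_formula, _term_block, _hat
from .phylo import bm_covariance, estimate_lambda, lambda_transform, read_tree
from .procrustes import gpa, species_means
from .simulate import SimulationParams, simulate_dataset
from .template import pteromyini_template

__all__ = ["RunConfig", "run_pipeline", "summarize_run", "PipelineResult"]


@dataclass
class RunConfig:
    # data source: simulation parameters, or explicit input paths
    simulate: dict | None = None
    landmarks_path: str | None = None
    landmarks_format: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # processing
    mirror: bool = True
    slide: bool = True
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 200
    model: str = "shape ~ diet * size"
    interaction: str = "always"  # always | auto | never
    n_perm: int = 1000
    disparity_stat: str = "variance"
    n_rep: int = 1000
    seed: int = 0
    outdir: str = "pteromorph_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("landmarks_path", "metadata_path", "tree_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"no simulation requested and {name} not set")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.interaction not in ("always", "auto", "never"):
            raise ValueError(f"interaction must be always/auto/never, got {self.interaction!r}")


@dataclass
class PipelineResult:
    manifest: dict
    aligned = None
    species_set = None
    morphospace = None
    fits: dict = field(default_factory=dict)
    lambda_hat: float = float("nan")
    dispersion = None
    allometry = None
    disparity_reports: dict = field(default_factory=dict)
    anova: dict = field(default_factory=dict)
    null_tables: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ols_residuals(Y, terms, diet, log_size):
    levels = sorted(set(diet)) if diet is not None else None
    cols = [np.ones((Y.shape[0], 1))]
    for t in terms:
        X, _ = _term_block(t, diet, log_size, levels)
        cols.append(X)
    X = np.column_stack(cols)
    return Y - _hat(X) @ Y


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    manifest: dict = {"config": asdict(config), "stages": [], "warnings": []}
    result = PipelineResult(manifest=manifest)
    template = pteromyini_template()

    def record(stage: str, outputs: dict, **info) -> None:
        entry = {"stage": stage, "outputs": {}, **info}
        for name, path in outputs.items():
            path = Path(path)
            entry["outputs"][name] = {
                "path": str(path.relative_to(outdir)),
                "sha256": _sha256(path),
            }
        manifest["stages"].append(entry)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- stage 1: data -------------------------------------------
        if config.simulate is not None:
            params = SimulationParams(**{**config.simulate, "seed": seeds[0]})
            configs, metadata, tree, _ = simulate_dataset(params, template)
            lm_path = outdir / "landmarks.csv"
            meta_path = outdir / "metadata.csv"
            tree_path = outdir / "tree.nwk"
            lio.write_landmarks(configs, lm_path)
            lio.write_metadata(metadata, meta_path)
            tree.write(path=str(tree_path), schema="newick")
            params.to_yaml(outdir / "sim_params.yaml")
            record(
                "data",
                {"landmarks": lm_path, "metadata": meta_path, "tree": tree_path},
                n_specimens=len(configs),
                n_species=len(metadata),
                seed=seeds[0],
                source="simulated",
            )
        else:
            configs = lio.read_landmarks(
                config.landmarks_path, config.landmarks_format, template
            )
            metadata = lio.read_metadata(config.metadata_path)
            tree = read_tree(config.tree_path)
            record(
                "data", {},
                n_specimens=len(configs), n_species=len(metadata), source="loaded",
            )

        # ---- stage 2: superimposition --------------------------------
        work_template = template
        if config.mirror:
            configs, work_template = lio.mirror_all(configs, template)
        aligned = gpa(
            configs,
            template=work_template,
            slide=config.slide,
            tol=config.gpa_tol,
            max_iter=config.gpa_max_iter,
        )
        result.aligned = aligned
        coords = pd.DataFrame(aligned.flat())
        coords.insert(0, "specimen", aligned.labels)
        coords.insert(1, "species", aligned.species)
        coords["centroid_size"] = aligned.centroid_sizes
        aligned_path = outdir / "aligned.csv"
        coords.to_csv(aligned_path, index=False, float_format="%.10g")
        record(
            "align", {"aligned": aligned_path},
            n_specimens=aligned.n, n_points=aligned.k,
            iterations=aligned.n_iterations, mirrored=config.mirror,
        )

        # ---- stage 3: species means + morphospace --------------------
        sp_set = species_means(aligned)
        result.species_set = sp_set
        space = pca(sp_set)
        result.morphospace = space
        scores = pd.DataFrame(
            space.scores, columns=[f"PC{i + 1}" for i in range(space.n_axes)]
        )
        scores.insert(0, "species", sp_set.labels)
        scores_path = outdir / "pca_scores.csv"
        scores.to_csv(scores_path, index=False, float_format="%.10g")
        var_path = outdir / "pca_variance.csv"
        pd.DataFrame(
            {
                "axis": [f"PC{i + 1}" for i in range(space.n_axes)],
                "proportion": space.variance_explained,
            }
        ).to_csv(var_path, index=False, float_format="%.10g")
        record(
            "pca", {"scores": scores_path, "variance": var_path},
            n_species=sp_set.n, n_axes=space.n_axes,
        )

        # ---- stage 4: comparative fits -------------------------------
        meta_idx = metadata.set_index("species")
        informative = [
            s for s in sp_set.labels
            if s in meta_idx.index and meta_idx.loc[s, "diet"] != "NoInfo"
        ]
        if len(informative) < len(sp_set.labels):
            warnings.warn(
                f"dropping {len(sp_set.labels) - len(informative)} species without "
                f"diet information; comparative n = {len(informative)}"
            )
        idx = [sp_set.labels.index(s) for s in informative]
        Y = sp_set.flat()[idx]
        logs = sp_set.log_sizes[idx]
        diets = meta_idx.loc[informative, "diet"].to_numpy()
        cov = bm_covariance(tree, taxa=informative)

        _, full_terms = parse_formula(config.model)
        resid = _ols_residuals(Y, full_terms, diets, logs)
        lam = estimate_lambda(resid, cov)
        result.lambda_hat = lam
        cov_l = lambda_transform(cov, lam)

        fits = {}
        fits["size ~ diet"] = pgls_fit(
            logs, "size ~ diet", cov_l, diet=diets,
            n_perm=config.n_perm, seed=seeds[1],
        )
        shape_terms = list(full_terms)
        if config.interaction == "never":
            shape_terms = [t for t in shape_terms if ":" not in t]
        elif config.interaction == "auto":
            if fits["size ~ diet"].p[0] > 0.05:
                shape_terms = [t for t in shape_terms if ":" not in t]
        shape_formula = "shape ~ " + " + ".join(shape_terms)
        fits[shape_formula] = pgls_fit(
            Y, shape_formula, cov_l, diet=diets, log_size=logs,
            n_perm=config.n_perm, seed=seeds[2],
        )
        fits["shape ~ size"] = pgls_fit(
            Y, "shape ~ size", cov_l, log_size=logs,
            n_perm=config.n_perm, seed=seeds[3],
        )
        result.fits = fits
        tables = []
        for name, fit in fits.items():
            tab = fit.anova_table()
            tab.insert(0, "model", name)
            tables.append(tab)
        anova_path = outdir / "pgls_tables.csv"
        pd.concat(tables, ignore_index=True).to_csv(
            anova_path, index=False, float_format="%.6g"
        )

        disp = pairwise_dispersion(
            Y, diets, cov_l, n_perm=config.n_perm, seed=seeds[4]
        )
        result.dispersion = disp
        disp_path = outdir / "pairwise_dispersion.csv"
        disp.to_csv(disp_path, index=False, float_format="%.6g")

        scores_a, _ = allometry_scores(Y, logs, cov_l)
        result.allometry = pd.DataFrame(
            {"species": informative, "log_size": logs, "regression_score": scores_a}
        )
        allo_path = outdir / "allometry_scores.csv"
        result.allometry.to_csv(allo_path, index=False, float_format="%.10g")
        record(
            "pgls",
            {"tables": anova_path, "dispersion": disp_path, "allometry": allo_path},
            n_species=len(informative), lambda_hat=lam,
            n_perm=config.n_perm, models=list(fits),
        )

        # ---- stage 5: observed disparity -----------------------------
        biomes = [b for b in lio.BIOME_LABELS if b in metadata.columns]
        reports = {}
        anova_res = {}
        for metric in ("shape", "size"):
            reps = [
                biome_disparity(sp_set, metadata, b, metric, config.disparity_stat)
                for b in biomes
            ]
            reports[metric] = {r.biome: r for r in reps}
            usable = [r for r in reps if r.defined and len(r.distances) >= 2]
            if len(usable) >= 2:
                anova_res[metric] = disparity_anova(usable)
        result.disparity_reports = reports
        result.anova = anova_res
        obs_rows = []
        for metric in reports:
            for r in reports[metric].values():
                obs_rows.append(
                    dict(metric=metric, biome=r.biome, n_species=r.n_species,
                         D=r.D_observed, low_power=r.low_power)
                )
        obs_path = outdir / "disparity_observed.csv"
        pd.DataFrame(obs_rows).to_csv(obs_path, index=False, float_format="%.8g")
        record(
            "disparity", {"observed": obs_path},
            anova={m: {"F": v[0], "p": v[1]} for m, v in anova_res.items()},
        )

        # ---- stage 6: richness null ----------------------------------
        defined = [
            r for m in reports for r in reports[m].values() if r.defined
        ]
        max_rich = max((r.n_species for r in defined), default=2)
        null_rows = []
        for j, metric in enumerate(("shape", "size")):
            table = richness_null(
                sp_set, metric, range(2, max_rich + 1),
                n_rep=config.n_rep, seed=seeds[5] + j, stat=config.disparity_stat,
            )
            result.null_tables[metric] = table
            slope, intercept, _ = richness_regression(table)
            for r in reports[metric].values():
                if not r.defined:
                    continue
                hyp = (
                    TROPICAL_HYPOTHESIS if r.biome in TROPICAL_BIOMES else TEMPERATE_HYPOTHESIS
                )
                biome_null_test(r, table, hyp)
                null_rows.append(
                    dict(metric=metric, biome=r.biome, n_species=r.n_species,
                         D=r.D_observed, side=r.side_tested, p=r.p_stated,
                         reverse_p=r.reverse_p, significant=r.significant,
                         null_slope=slope, null_intercept=intercept)
                )
        null_path = outdir / "disparity_null_tests.csv"
        pd.DataFrame(null_rows).to_csv(null_path, index=False, float_format="%.8g")
        nt_path = outdir / "null_table_shape.csv"
        result.null_tables["shape"].to_csv(nt_path, index=False, float_format="%.8g")
        nt2_path = outdir / "null_table_size.csv"
        result.null_tables["size"].to_csv(nt2_path, index=False, float_format="%.8g")
        record(
            "null",
            {"tests": null_path, "null_shape": nt_path, "null_size": nt2_path},
            n_rep=config.n_rep, max_richness=max_rich,
        )

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    return result


def summarize_run(manifest_or_dir) -> str:
    """Human-readable report of a completed run, built from its artifacts."""
    path = Path(manifest_or_dir)
    outdir = path if path.is_dir() else path.parent
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {outdir}")
    manifest = json.loads(manifest_path.read_text())
    done = {s["stage"] for s in manifest["stages"]}
    lines = ["pteromorph run summary", "=" * 30, ""]
    incomplete = {"data", "align", "pca", "pgls", "disparity", "null"} - done
    if incomplete:
        lines.append(f"!! incomplete run; missing stages: {sorted(incomplete)}")
        lines.append("")
    for stage in manifest["stages"]:
        if stage["stage"] == "pgls":
            lines.append(f"Pagel's lambda (residuals of the full model): {stage['lambda_hat']:.4f}")
            lines.append("")
    if "pgls" in done:
        tabs = pd.read_csv(outdir / "pgls_tables.csv")
        for model, tab in tabs.groupby("model", sort=False):
            lines.append(model)
            lines.append(
                tab.drop(columns="model").to_string(
                    index=False, float_format=lambda v: f"{v:.5g}"
                )
            )
            lines.append("")
    if "null" in done:
        tests = pd.read_csv(outdir / "disparity_null_tests.csv")
        for metric, tab in tests.groupby("metric"):
            lines.append(f"{metric} disparity by biome (richness-conditioned null)")
            cols = ["biome", "n_species", "D", "side", "p", "reverse_p", "significant"]
            lines.append(tab[cols].to_string(index=False, float_format=lambda v: f"{v:.5g}"))
            lines.append("")
    if "disparity" in done:
        for stage in manifest["stages"]:
            if stage["stage"] == "disparity":
                for metric, res in stage.get("anova", {}).items():
                    lines.append(
                        f"ANOVA of {metric} distances across biomes: "
                        f"F = {float(res['F']):.4g}, p = {float(res['p']):.4g}"
                    )
        lines.append("")
    if manifest.get("warnings"):
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in manifest["warnings"])
    return "\n".join(lines) + "\n"
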