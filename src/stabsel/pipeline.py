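"""End-to-end analysis pipeline and result writers.

Wires the stages together — load, standardize, gradients, permutation
p-values, canonical analysis, peak region, cross-sex interaction — and
writes each published-table shape as a tidy CSV plus a machine-readable
run manifest. Every stochastic step draws from the single run seed, so
re-running with the same manifest reproduces all outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .canonical import canonical_rotation, theta_projection
from .data_model import (
    ConfigurationError,
    PairDataset,
    relative_fitness,
    standardize,
)
from .gradients import GradientSet, cross_sex_model, fit_gradients
from .peak_region import bootstrap_peak_region, surface_grid, tps_fit
from .resampling import permute_gradient_pvalues, reynolds_lambda_test

logger = logging.getLogger("stabsel")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Settings for one full analysis run."""

    output_dir: Path
    seed: int
    n_permutations: int = 10_000
    n_bootstrap: int = 1000
    retain: float = 0.95
    n_directions: int = 10_000
    peak_axes: tuple[int, int] | None = None  # 0-based canonical axes; None = two most stabilizing
    grid_resolution: int = 50
    overwrite: bool = False
    sexes: tuple[str, ...] = ("male", "female")
    cross_sex: bool = True

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)


def _gradient_rows(
    sex: str, gs: GradientSet, perm_lin, perm_quad, seed: int
) -> list[dict]:
    """Tidy rows (one per gradient) merging estimates and p-values."""
    pmap = {r.term.label(): r for r in perm_lin + perm_quad}
    rows = []
    names = gs.trait_names
    for j, nm in enumerate(names):
        r = pmap.get(f"linear:{nm}")
        rows.append(dict(sex=sex, term_type="linear", trait_1=nm, trait_2="",
                         estimate=gs.beta[j],
                         p_value=r.p_two_tailed if r else np.nan,
                         n_iterations=r.n_iter if r else 0, seed=seed))
    for j, nm in enumerate(names):
        r = pmap.get(f"quadratic:{nm}")
        rows.append(dict(sex=sex, term_type="quadratic", trait_1=nm, trait_2=nm,
                         estimate=gs.gamma[j, j],
                         p_value=r.p_two_tailed if r else np.nan,
                         n_iterations=r.n_iter if r else 0, seed=seed))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = pmap.get(f"correlational:{names[i]}:{names[j]}")
            rows.append(dict(sex=sex, term_type="correlational",
                             trait_1=names[i], trait_2=names[j],
                             estimate=gs.gamma[i, j],
                             p_value=r.p_two_tailed if r else np.nan,
                             n_iterations=r.n_iter if r else 0, seed=seed))
    return rows


def _check_output(path: Path, overwrite: bool) -> Path:
    if path.exists() and not overwrite:
        raise ConfigurationError(
            f"{path} exists; pass overwrite=True (--overwrite) to replace it")
    return path


def run_full_analysis(dataset: PairDataset, config: RunConfig) -> dict:
    """Run every stage on a loaded pair dataset and write all artifacts.

    Returns a result bundle with the per-sex gradient sets, canonical
    decompositions, peak regions, the interaction matrix, and the paths
    of everything written.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31))
                   for name in ("perm_male", "perm_female", "perm_cross",
                                "reynolds_male", "reynolds_female",
                                "peak_male", "peak_female")}

    logger.info("loaded %d pairs (%d successes, %d dropped at load)",
                dataset.n_pairs, dataset.n_success, dataset.n_dropped)
    w = relative_fitness(dataset.success).w

    bundle: dict = {"paths": {}, "gradients": {}, "canonical": {},
                    "peak_region": {}}
    gradient_rows: list[dict] = []
    canonical_rows: list[dict] = []

    std = {
        "male": standardize(dataset.male_traits, dataset.male_trait_names),
        "female": standardize(dataset.female_traits, dataset.female_trait_names),
    }

    for sex in config.sexes:
        z = std[sex].z
        names = std[sex].trait_names
        gs = fit_gradients(z, w, names)
        logger.info("%s: n=%d, r2 linear=%.3f quadratic=%.3f",
                    sex, gs.n, gs.r2_linear, gs.r2_quadratic)
        perm_lin = permute_gradient_pvalues(
            z, w, model="linear", n_iter=config.n_permutations,
            seed=stage_seeds[f"perm_{sex}"], trait_names=names)
        perm_quad = permute_gradient_pvalues(
            z, w, model="quadratic", n_iter=config.n_permutations,
            seed=stage_seeds[f"perm_{sex}"], trait_names=names)
        gradient_rows.extend(_gradient_rows(
            sex, gs, perm_lin, perm_quad, stage_seeds[f"perm_{sex}"]))
        bundle["gradients"][sex] = gs

        M, lam = canonical_rotation(gs.gamma)
        theta = theta_projection(M, gs.beta)
        rey = reynolds_lambda_test(
            z, w, M, n_iter=config.n_permutations,
            seed=stage_seeds[f"reynolds_{sex}"])
        for i in range(M.shape[0]):
            row = dict(sex=sex, axis=f"m{i + 1}", theta=theta[i],
                       eigenvalue=lam[i],
                       p_eigenvalue=rey[i].p_two_tailed,
                       n_iterations=rey[i].n_iter,
                       seed=stage_seeds[f"reynolds_{sex}"])
            row.update({f"loading_{nm}": M[i, j]
                        for j, nm in enumerate(names)})
            canonical_rows.append(row)
        bundle["canonical"][sex] = dict(M=M, lam=lam, theta=theta,
                                        reynolds=rey)

        # peak region on the two most stabilizing canonical axes
        axes = config.peak_axes if config.peak_axes is not None else (
            int(np.argsort(lam)[1]), int(np.argsort(lam)[0]))
        Y = z @ M.T
        scores = Y[:, list(axes)]
        region = bootstrap_peak_region(
            scores, w, B=config.n_bootstrap, retain=config.retain,
            n_directions=config.n_directions,
            seed=stage_seeds[f"peak_{sex}"])
        bundle["peak_region"][sex] = region
        logger.info("%s peak: centroid %s, %.1f%% boundary refits",
                    sex, np.round(region.centroid, 3),
                    100 * region.boundary_fraction)

        axis_names = [f"m{a + 1}" for a in axes]
        pd.DataFrame(region.maxima_cloud, columns=axis_names).to_csv(
            _check_output(out / f"peak_maxima_{sex}.csv", config.overwrite),
            index=False)
        pd.DataFrame(region.hull_vertices, columns=axis_names).to_csv(
            _check_output(out / f"peak_hull_{sex}.csv", config.overwrite),
            index=False)
        spline = tps_fit(scores, w, smoothing="gcv")
        grid = surface_grid(spline, config.grid_resolution,
                            np.column_stack([scores.min(0), scores.max(0)]))
        pd.DataFrame(grid, columns=axis_names + ["fitness"]).to_csv(
            _check_output(out / f"surface_grid_{sex}.csv", config.overwrite),
            index=False)
        peak_meta = dict(
            sex=sex, axes=axis_names,
            centroid={a: float(c) for a, c in zip(axis_names, region.centroid)},
            retain=region.retain,
            boundary_fraction=region.boundary_fraction,
            nonconcave_fraction=region.nonconcave_fraction,
            degenerate=region.degenerate,
            tps_smoothing=spline.smoothing, tps_gcv=spline.gcv_score,
        )
        with open(_check_output(out / f"peak_summary_{sex}.json",
                                config.overwrite), "w") as fh:
            json.dump(peak_meta, fh, indent=2)

    interaction_rows: list[dict] = []
    if config.cross_sex and len(config.sexes) == 2:
        set_m, set_f, inter = cross_sex_model(
            std["male"].z, std["female"].z, w,
            std["male"].trait_names, std["female"].trait_names)
        perm_cross = permute_gradient_pvalues(
            (std["male"].z, std["female"].z), w, model="cross_sex",
            n_iter=config.n_permutations, seed=stage_seeds["perm_cross"],
            trait_names=(std["male"].trait_names, std["female"].trait_names))
        pmap = {r.term.label(): r for r in perm_cross}
        for i, fn in enumerate(inter.female_names):
            for j, mn in enumerate(inter.male_names):
                r = pmap.get(f"cross_sex:female:{fn}:male:{mn}")
                interaction_rows.append(dict(
                    sex="both", term_type="cross_sex",
                    trait_1=f"female:{fn}", trait_2=f"male:{mn}",
                    estimate=inter.values[i, j],
                    p_value=r.p_two_tailed if r else np.nan,
                    n_iterations=r.n_iter if r else 0,
                    seed=stage_seeds["perm_cross"]))
        bundle["interaction"] = inter
        bundle["cross_sex_gradients"] = (set_m, set_f)

    tables = {
        "gradients.csv": pd.DataFrame(gradient_rows),
        "canonical.csv": pd.DataFrame(canonical_rows),
    }
    if interaction_rows:
        tables["interaction.csv"] = pd.DataFrame(interaction_rows)
    for name, df in tables.items():
        path = _check_output(out / name, config.overwrite)
        df.to_csv(path, index=False)
        bundle["paths"][name] = path

    manifest = dict(
        package_version=__version__,
        seed=config.seed,
        stage_seeds=stage_seeds,
        n_pairs=dataset.n_pairs,
        n_success=dataset.n_success,
        n_dropped=dataset.n_dropped,
        n_permutations=config.n_permutations,
        n_bootstrap=config.n_bootstrap,
        retain=config.retain,
        n_directions=config.n_directions,
        outputs=sorted(p.name for p in out.iterdir()),
    )
    with open(_check_output(out / "manifest.json", config.overwrite), "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
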