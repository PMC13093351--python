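"""Range-wide offset projection, latitude regressions, binned maps, pipeline.

Latitude is signed (southern hemisphere negative) throughout; regression
slopes are reported per degree of (signed) latitude and the output
tables say so in their headers, so "offset increases northward" means a
negative relationship with latitude in the paperly sense and a positive
slope against degrees-north here.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import climate_io as cio
from . import gea, genotypes, offset_gf, offset_lfmm, synthetic
from .climate_io import Raster, RasterSet, Scaler
from .synthetic import CLIMATE_VARS

__all__ = [
    "RegressionSummary",
    "project_offsets",
    "regress_offset_latitude",
    "bin_offsets",
    "PipelineConfig",
    "run_pipeline",
]


def _rasters_to_table(rs: RasterSet, cells: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({v: rs[v].data[cells] for v in rs.variables})


def project_offsets(current: RasterSet, future: RasterSet, mask: Raster,
                    scaler: Scaler, lfmm_B: np.ndarray | None = None,
                    gf_model: offset_gf.TurnoverModel | None = None
                    ) -> dict[str, Raster]:
    """Per-cell offsets across a masked range, plus a novelty raster.

    Returns a dict with an offset raster per requested method
    (``"lfmm"``, ``"gf"``) and a ``"novelty"`` raster flagging cells
    whose current or future climate falls outside the training envelope
    (projection there relies on the turnover plateaus / linear
    extrapolation and is less trustworthy). Out-of-mask cells are nodata.
    """
    template = current.template()
    for name, rs in (("future", future.template()), ("mask", mask)):
        if not rs.aligned_with(template):
            raise ValueError(f"{name} raster grid is not aligned with current")
    in_mask = np.isfinite(mask.data) & (mask.data > 0)
    if not in_mask.any():
        warnings.warn("range mask excludes every cell; outputs are all nodata")
    cur_tab = _rasters_to_table(current, in_mask)
    fut_tab = _rasters_to_table(future, in_mask)
    usable = ~(cur_tab.isna().any(axis=1) | fut_tab.isna().any(axis=1))

    novelty = scaler.novelty(cur_tab) | scaler.novelty(fut_tab)
    cur_s = scaler.transform_table(cur_tab[usable])
    fut_s = scaler.transform_table(fut_tab[usable])

    def paint(values_usable: np.ndarray) -> Raster:
        flat = np.full(usable.shape, np.nan)
        flat[usable.to_numpy()] = values_usable
        grid = np.full(template.shape, np.nan)
        grid[in_mask] = flat
        return template.copy_with(grid)

    out: dict[str, Raster] = {}
    if lfmm_B is not None:
        out["lfmm"] = paint(offset_lfmm.genetic_gap(
            lfmm_B, cur_s[list(scaler.variables)].to_numpy(),
            fut_s[list(scaler.variables)].to_numpy()))
    if gf_model is not None:
        out["gf"] = paint(offset_gf.gf_offset(gf_model, cur_s, fut_s))
    out["novelty"] = paint(novelty[usable.to_numpy()].astype(float))
    return out


@dataclass
class RegressionSummary:
    """OLS of site-mean offset on latitude for one site group."""

    group: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    tier: str            # solid (p<=0.05) | dashed (0.05<p<=0.1) | none
    n_sites: int


def _tier(p: float) -> str:
    if p <= 0.05:
        return "solid"
    if p <= 0.1:
        return "dashed"
    return "none"


def regress_offset_latitude(site_means: pd.DataFrame,
                            design: synthetic.SamplingDesign,
                            group_by: str | None = "elevation_class"
                            ) -> list[RegressionSummary]:
    """Regress site-mean offsets on signed latitude, per elevation class.

    ``site_means`` needs columns ``site_id`` and ``mean_offset``. With
    ``group_by=None`` a single all-sites regression is returned.
    """
    df = site_means.merge(design.sites[["site_id", "latitude",
                                        "elevation_class"]], on="site_id")
    if group_by is None:
        groups = [("all", df)]
    else:
        groups = [(str(g), sub) for g, sub in df.groupby(group_by)]
    out = []
    for name, sub in groups:
        if len(sub) < 3:
            raise ValueError(f"group '{name}' has {len(sub)} sites; need >= 3")
        lat = sub["latitude"].to_numpy(dtype=float)
        if np.ptp(lat) == 0:
            raise ValueError(f"group '{name}': latitude is constant")
        X = sm.add_constant(lat)
        fit = sm.OLS(sub["mean_offset"].to_numpy(dtype=float), X).fit()
        p = float(fit.pvalues[1])
        out.append(RegressionSummary(
            group=name, slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared), p_value=p, tier=_tier(p),
            n_sites=int(len(sub))))
    return out


def bin_offsets(raster: Raster, n_bins: int = 8, scheme: str = "quantile"
                ) -> tuple[Raster, pd.DataFrame]:
    """Classify an offset raster into ordered bins for map legends.

    Returns the classified raster (classes 1..n_bins, nodata preserved)
    and a legend table of bin edges. A constant raster under the
    quantile scheme collapses to a single class with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = raster.data[np.isfinite(raster.data)]
    if vals.size == 0:
        raise ValueError("raster has no finite cells to bin")
    if scheme == "quantile":
        edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    elif scheme == "equal":
        edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning scheme '{scheme}'")
    edges = np.unique(edges)
    if len(edges) < 3:
        warnings.warn("constant raster: single bin produced")
        classes = np.where(np.isfinite(raster.data), 1.0, np.nan)
        legend = pd.DataFrame({"class": [1], "lower": [vals.min()],
                               "upper": [vals.max()]})
        return raster.copy_with(classes), legend
    inner = edges[1:-1]
    classes = np.full(raster.shape, np.nan)
    finite = np.isfinite(raster.data)
    classes[finite] = np.digitize(raster.data[finite], inner, right=True) + 1
    legend = pd.DataFrame({"class": np.arange(1, len(edges)),
                           "lower": edges[:-1], "upper": edges[1:]})
    return raster.copy_with(classes), legend


# ---------------------------------------------------------------------------
# end-to-end pipeline


_REQUIRED_FIELDS = ("seed", "n_pairs", "n_per_site", "n_neutral",
                    "n_adaptive", "K")


@dataclass
class PipelineConfig:
    seed: int = 42
    n_pairs: int = 10
    n_ungrouped: int = 0
    n_per_site: int = 25
    n_neutral: int = 1900
    n_adaptive: int = 100
    K: int = 3
    fdr_q: float = 0.01
    maf_threshold: float = 0.05
    gf_trees: int = 500
    mask_elevation_m: float = 200.0
    scenarios: list[str] = field(default_factory=lambda: [
        sc.key for sc in synthetic.default_climate_config().scenarios])
    outdir: str = "genoffset_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        missing = [k for k in _REQUIRED_FIELDS if k not in d]
        if missing:
            raise ValueError(f"config missing required field(s): {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config has unknown field(s): {sorted(unknown)}")
        cfg = cls(**d)
        valid = {sc.key for sc in synthetic.default_climate_config().scenarios}
        bad = [s for s in cfg.scenarios if s not in valid]
        if bad:
            raise ValueError(
                f"config field 'scenarios' lists undefined scenario(s) {bad}; "
                f"valid: {sorted(valid)}")
        if not cfg.scenarios:
            raise ValueError("config field 'scenarios' must not be empty")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study end to end and write the output tree.

    simulate → extract/scale → GEA → candidates → both offsets → site
    means → latitude regressions → raster projections; returns (and
    writes) a manifest with the seeds, stages, outputs and checksums.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate-design"
    try:
        ccfg = synthetic.default_climate_config()
        design = synthetic.generate_design(n_pairs=config.n_pairs,
                                           n_ungrouped=config.n_ungrouped,
                                           seed=config.seed)
        stage = "simulate-climate"
        trees, rs_cur, dem = synthetic.generate_climate(
            design, ccfg, seed=config.seed + 1, n_per_site=config.n_per_site)
        stage = "simulate-genotypes"
        G, truth = synthetic.generate_genotypes(
            design, trees, n_neutral=config.n_neutral,
            n_adaptive=config.n_adaptive, seed=config.seed + 2)
        stage = "maf-filter"
        G, maf_report = genotypes.maf_filter(G, config.maf_threshold)
        stage = "scale-climate"
        scaler = cio.fit_scaler(trees, variables=list(CLIMATE_VARS))
        E = scaler.transform_table(trees)[list(CLIMATE_VARS)]
        stage = "gea"
        model = gea.fit_latent_model(G, E, K=config.K)
        assoc = gea.association_test(G, E, model.U)
        hits: set[str] = set()
        for v in CLIMATE_VARS:
            pv = assoc.p_calibrated[v]
            hits |= set(np.asarray(pv.index)[gea.bh_fdr(pv.to_numpy(),
                                                        config.fdr_q)])
        candidates = gea.CandidateSet.from_ids(sorted(hits), "supplemental")
        if len(candidates) == 0:
            raise RuntimeError("no candidate loci passed the FDR threshold")
        stage = "offset-models"
        cand_idx = [G.locus_ids.index(l) for l in candidates.locus_ids]
        B_cand = model.B[:, cand_idx]
        G_cand = G.subset_loci(candidates.locus_ids)
        predictors = E.copy()
        for k in range(model.K):
            predictors[f"U{k+1}"] = model.U[:, k]
        gf_model = offset_gf.fit_turnover(
            G_cand, predictors, n_trees=config.gf_trees,
            seed=config.seed + 3, climate_predictors=list(CLIMATE_VARS))
        stage = "offsets"
        mask = dem.copy_with(
            (dem.data >= config.mask_elevation_m).astype(float))
        files: list[Path] = []
        site_tables = []
        regressions = []
        for key in config.scenarios:
            fut_trees = synthetic.generate_future(trees, key, ccfg)
            Ef = scaler.transform_table(fut_trees)[list(CLIMATE_VARS)]
            per_tree = pd.DataFrame({
                "tree_id": trees["tree_id"], "site_id": trees["site_id"],
                "lfmm": offset_lfmm.genetic_gap(B_cand, E.to_numpy(),
                                                Ef.to_numpy()),
                "gf": offset_gf.gf_offset(gf_model, E, Ef),
            })
            for method in ("lfmm", "gf"):
                sm_tab = offset_lfmm.site_mean_offsets(
                    per_tree.rename(columns={method: "offset"}))
                sm_tab.insert(0, "scenario", key)
                sm_tab.insert(1, "method", method)
                site_tables.append(sm_tab)
                for cls_group in regress_offset_latitude(sm_tab, design):
                    rec = asdict(cls_group)
                    rec.update(scenario=key, method=method)
                    regressions.append(rec)
            fut_rs = synthetic.generate_future(rs_cur, key, ccfg,
                                               elevation=dem)
            proj = project_offsets(rs_cur, fut_rs, mask, scaler,
                                   lfmm_B=B_cand, gf_model=gf_model)
            for name, raster in proj.items():
                p = out / f"offset_{name}_{key}.asc"
                cio.write_ascii_grid(raster, p)
                files.append(p)
        stage = "write-tables"
        site_df = pd.concat(site_tables, ignore_index=True)
        reg_df = pd.DataFrame(regressions)
        reg_df.attrs["note"] = "slope per degree signed latitude (south < 0)"
        writes = {
            "design.csv": design.sites,
            "trees_climate.csv": trees,
            "truth_table.csv": truth.loci,
            "maf_report.tsv": maf_report,
            "candidates.tsv": candidates.table,
            "site_mean_offsets.tsv": site_df,
            "regressions.tsv": reg_df,
        }
        for fname, df in writes.items():
            p = out / fname
            sep = "\t" if fname.endswith(".tsv") else ","
            df.to_csv(p, sep=sep, index=False)
            files.append(p)
        scaler.save(out / "scaler.json")
        files.append(out / "scaler.json")
        gf_model.to_json(out / "turnover_model.json")
        files.append(out / "turnover_model.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "package": "genoffset",
        "seed": config.seed,
        "config": asdict(config),
        "n_scenarios": len(config.scenarios),
        "n_candidates": len(candidates),
        "checksums": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
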