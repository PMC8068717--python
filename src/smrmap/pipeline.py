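"""Configuration-driven end-to-end runs and table/map exports.

A run reads the area tables (counts, populations, covariates), the
neighbour list plus sea-route edges, optionally aggregates areas, then
per gender x age stratum computes raw SMRs, fits the smoothing model
(covariate-free BYM) for smoothed SMRs, and fits the decile model
unadjusted and/or adjusted for rate-ratio tables; the adjusted fit also
yields residual SMRs.  Everything lands in an output directory as CSV /
GeoJSON with a JSON manifest recording seed, config hash, record
accounting and convergence.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import (
    COVARIATE_COLUMNS,
    assign_deciles,
    build_design,
    transform_covariates,
)
from .graph import (
    AreaGraph,
    add_edges,
    aggregate_areas,
    read_edge_csv,
    read_merge_map,
    read_neighbor_list,
    validate_graph,
)
from .model import BYMModel, BYMSpec, MCMCConfig
from .standardize import (
    SMRTable,
    categorize_smr,
    expected_counts,
    national_rates,
    range_ratio,
    raw_smr,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_map_geojson", "write_rr_table",
           "exclusion_accounting", "age_group_bands"]

DEFAULT_STRATA = tuple(
    f"{g}:{a}" for g in ("male", "female") for a in ("all", "0-39", "40-59", "60+")
)

# suggested map colour key: 3 blues below, pale yellow middle, 3 browns above
CATEGORY_COLORS = (
    "#2166ac", "#67a9cf", "#d1e5f0", "#ffffbf",
    "#d8b365", "#a6611a", "#7b3014",
)


@dataclass
class RunConfig:
    """Inputs, strata, model modes and sampler settings for one run."""

    counts: str
    population: str
    covariates: str
    neighbors: str
    seed: int
    extra_edges: str | None = None
    merge_map: str | None = None
    polygons: str | None = None
    strata: tuple[str, ...] = DEFAULT_STRATA
    modes: tuple[str, ...] = ("unadjusted", "adjusted")
    output_dir: str = "smrmap_out"
    chains: int = 2
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 1
    tau_prior_rate: float = 5e-5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("strata", "modes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def mcmc(self) -> MCMCConfig:
        return MCMCConfig(
            seed=self.seed, chains=self.chains, iterations=self.iterations,
            burn_in=self.burn_in, thin=self.thin,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def band_start(band: str) -> int:
    return int(str(band).split("-")[0].rstrip("+"))


def age_group_bands(group: str, bands) -> list[str]:
    """Bands belonging to an age-group union ('all', '0-39', '40-59', '60+')."""
    if group == "all":
        return list(bands)
    if group.endswith("+"):
        lo, hi = int(group[:-1]), 10**9
    else:
        lo, hi = (int(x) for x in group.split("-"))
    out = [b for b in bands if lo <= band_start(b) <= hi]
    if not out:
        raise ValueError(f"age group {group!r} matches no bands in {list(bands)}")
    return out


def exclusion_accounting(counts: pd.DataFrame, known_areas: set[str]) -> dict:
    """Events that cannot be assigned to an area (or lack age data).

    Returns totals, the excluded event count and its percentage (one
    decimal, as commonly reported).
    """
    c = counts.copy()
    bad = (
        c["area_id"].isna()
        | (c["area_id"].astype(str).str.strip() == "")
        | ~c["area_id"].astype(str).isin(known_areas)
        | c["age_band"].isna()
    )
    total = int(c["count"].sum())
    excluded = int(c.loc[bad, "count"].sum())
    included = total - excluded
    return {
        "total_events": total,
        "excluded_events": excluded,
        "included_events": included,
        "excluded_pct": round(100.0 * excluded / total, 1) if total else 0.0,
    }


def _load_inputs(config: RunConfig):
    graph = read_neighbor_list(config.neighbors)
    if config.extra_edges:
        graph = add_edges(graph, read_edge_csv(config.extra_edges))
    counts = pd.read_csv(config.counts, dtype={"area_id": str})
    population = pd.read_csv(config.population, dtype={"area_id": str})
    covariates = pd.read_csv(config.covariates, dtype={"area_id": str})
    if config.merge_map:
        merge = read_merge_map(config.merge_map)
        graph, (counts, population) = aggregate_areas(
            graph, merge, [counts, population]
        )
        # covariate rows must exist for the aggregated ids (density is not
        # additive); unmerged rows pass through
        covariates = covariates[covariates["area_id"].isin(graph.area_ids)]
    return graph, counts, population, covariates


def _stratum_tables(counts, population, gender: str, group: str, graph):
    bands = sorted(population["age_band"].unique(), key=band_start)
    use = age_group_bands(group, bands)
    genders = [gender] if gender != "total" else list(counts["gender"].unique())
    c = counts[counts.gender.isin(genders) & counts.age_band.isin(use)]
    p = population[
        population.gender.isin(genders) & population.age_band.isin(use)
    ]
    # reference rates per gender x band from the pooled study region itself
    e_total = pd.Series(0.0, index=list(graph.area_ids))
    for g in genders:
        cg = c[c.gender == g]
        pg = p[p.gender == g]
        pooled_counts = cg.groupby("age_band")["count"].sum().reindex(use).fillna(0)
        pooled_py = pg.groupby("age_band")["person_years"].sum().reindex(use).fillna(0)
        rates = national_rates(pooled_counts, pooled_py)
        pop_wide = (
            pg.pivot_table(index="area_id", columns="age_band",
                           values="person_years", aggfunc="sum")
            .reindex(list(graph.area_ids))
            .fillna(0.0)
        )
        for b in use:
            if b not in pop_wide.columns:
                pop_wide[b] = 0.0
        e_total = e_total.add(expected_counts(pop_wide[use], rates), fill_value=0.0)
    observed = (
        c.groupby("area_id")["count"].sum().reindex(list(graph.area_ids)).fillna(0)
    )
    return observed, e_total


def _smr_frame(values: pd.Series, stratum: str, kind: str) -> pd.DataFrame:
    table = SMRTable(
        tuple(values.index), values.to_numpy(float),
        ~np.isfinite(values.to_numpy(float)), stratum,
    )
    df = table.to_frame()
    df.insert(1, "kind", kind)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all strata x modes; return an output bundle description."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, counts, population, covariates = _load_inputs(config)
    graph_report = validate_graph(graph)
    accounting = exclusion_accounting(counts, set(graph.area_ids))
    counts = counts[counts["area_id"].isin(graph.area_ids) & counts["age_band"].notna()]

    cov = covariates.set_index("area_id").reindex(list(graph.area_ids))
    deciles = assign_deciles(cov["density"])
    z = transform_covariates(cov[list(COVARIATE_COLUMNS)])

    spec = BYMSpec(tau_b=config.tau_prior_rate)
    mcmc = config.mcmc()
    rr_rows = []
    smr_frames = []
    range_report = {}
    convergence = {}
    outputs = []

    for stratum in config.strata:
        gender, group = stratum.split(":")
        observed, expected = _stratum_tables(
            counts, population, gender, group, graph
        )
        raw = raw_smr(
            observed.to_numpy(), expected.to_numpy(),
            tuple(graph.area_ids), stratum,
        )
        raw_df = raw.to_frame()
        raw_df.insert(1, "kind", "raw")
        smr_frames.append(raw_df)
        range_report.setdefault(stratum, {})["raw"] = range_ratio(
            raw.defined_values()
        )

        # covariate-free smoothing fit -> smoothed SMRs
        smooth_model = BYMModel.from_tables(observed, expected, graph, spec=spec)
        smooth_res = smooth_model.fit(mcmc)
        smoothed = smooth_res.smoothed_smr()
        sm_df = _smr_frame(smoothed, stratum, "smoothed")
        smr_frames.append(sm_df)
        range_report[stratum]["smoothed"] = range_ratio(smoothed.to_numpy())
        convergence[f"{stratum}|smoothing"] = smooth_res.diagnostics().to_dict(
            orient="records"
        )

        for mode in config.modes:
            design, names = build_design(
                deciles, z, adjusted=(mode == "adjusted")
            )
            model = BYMModel.from_tables(
                observed, expected, graph, design, names, spec
            )
            res = model.fit(mcmc)
            rr = res.rate_ratios()
            for _, row in rr.iterrows():
                rr_rows.append(
                    {"stratum": stratum, "mode": mode, **row.to_dict()}
                )
            convergence[f"{stratum}|{mode}"] = res.diagnostics().to_dict(
                orient="records"
            )
            if mode == "adjusted":
                resid = res.residual_smr()
                rs_df = _smr_frame(resid, stratum, "residual")
                smr_frames.append(rs_df)
                range_report[stratum]["residual"] = range_ratio(resid.to_numpy())
        logger.info("stratum %s done (%.1fs elapsed)", stratum, time.time() - t0)

    smr_path = outdir / "smr_tables.csv"
    pd.concat(smr_frames, ignore_index=True).to_csv(smr_path, index=False)
    outputs.append(str(smr_path))
    rr_path = outdir / "rate_ratios.csv"
    write_rr_table(rr_rows, rr_path)
    outputs.append(str(rr_path))
    rng_path = outdir / "range_ratios.json"
    rng_path.write_text(json.dumps(range_report, indent=1))
    outputs.append(str(rng_path))

    if config.polygons:
        smoothed_all = [f for f in smr_frames if f["kind"].iloc[0] == "smoothed"]
        geo_path = outdir / "smoothed_smr_map.geojson"
        write_map_geojson(config.polygons, smoothed_all[0], geo_path)
        outputs.append(str(geo_path))

    non_converged = [
        key
        for key, diag in convergence.items()
        if any(not d["converged"] for d in diag)
    ]
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "graph": graph_report,
        "record_accounting": accounting,
        "strata": list(config.strata),
        "modes": list(config.modes),
        "mcmc": {
            "chains": config.chains,
            "iterations": config.iterations,
            "burn_in": config.burn_in,
            "thin": config.thin,
        },
        "convergence": convergence,
        "non_converged": non_converged,
        "status": "NON-CONVERGED" if non_converged else "ok",
        "elapsed_seconds": round(time.time() - t0, 2),
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["exit_code"] = 2 if non_converged else 0
    return manifest


def write_rr_table(rows, path: str | Path) -> pd.DataFrame:
    """Long-format rate-ratio CSV mirroring the before/after tables.

    One row per stratum x mode x coefficient; the reference decile is
    included with RR 1 and empty interval fields.
    """
    decile_names = {
        1: "most urban", 2: "2nd most urban", 3: "3rd most urban",
        4: "4th most urban", 5: "5th most urban", 6: "5th most rural",
        7: "4th most rural", 8: "3rd most rural", 9: "2nd most rural",
        10: "most rural",
    }
    records = []
    seen_strata = []
    for r in rows:
        key = (r["stratum"], r["mode"])
        if key not in seen_strata:
            seen_strata.append(key)
            records.append(
                {
                    "stratum": r["stratum"], "mode": r["mode"],
                    "decile": decile_names[1], "coefficient": "reference",
                    "rr": 1.0, "ci_low": "", "ci_high": "", "significant": "",
                }
            )
        name = r["coefficient"]
        decile = (
            decile_names[int(name.split("_")[1])]
            if name.startswith("decile_")
            else name
        )
        records.append(
            {
                "stratum": r["stratum"], "mode": r["mode"], "decile": decile,
                "coefficient": name, "rr": r["rr"], "ci_low": r["ci_low"],
                "ci_high": r["ci_high"], "significant": bool(r["significant"]),
            }
        )
    df = pd.DataFrame(records)
    df.to_csv(path, index=False)
    return df


def write_map_geojson(
    polygons: str | Path | dict, smr_table: pd.DataFrame, path: str | Path
) -> dict:
    """Attach SMR values and 7-bin categories to polygon features.

    ``polygons`` is a GeoJSON FeatureCollection whose features carry an
    ``area_id`` property.  Features without a matching SMR row (or SMR
    rows without a polygon) are reported and skipped.
    """
    if not isinstance(polygons, dict):
        polygons = json.loads(Path(polygons).read_text())
    values = smr_table.set_index("area_id")
    features = []
    matched = set()
    for feat in polygons.get("features", []):
        area = str(feat.get("properties", {}).get("area_id", ""))
        if area not in values.index:
            logger.warning("polygon %r has no SMR value; omitted", area)
            continue
        row = values.loc[area]
        smr = float(row["smr"])
        if not np.isfinite(smr):
            logger.warning("area %r has undefined SMR; omitted from map", area)
            continue
        label, idx = categorize_smr(smr)
        props = dict(feat.get("properties", {}))
        props.update(
            {
                "smr": smr,
                "category_index": idx,
                "category_label": label,
                "color": CATEGORY_COLORS[idx - 1],
            }
        )
        features.append({**feat, "properties": props})
        matched.add(area)
    missing = set(values.index) - matched
    for area in sorted(missing):
        logger.warning("area %r has no polygon; omitted from map", area)
    out = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(out))
    return out


def write_dataset(ds, outdir: str | Path) -> dict[str, str]:
    """Persist a synthetic dataset in the formats the pipeline reads."""
    from .graph import write_neighbor_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.csv",
        "population": outdir / "population.csv",
        "covariates": outdir / "covariates.csv",
        "neighbors": outdir / "neighbors.gal",
        "truth": outdir / "truth.json",
    }
    ds.counts.to_csv(paths["counts"], index=False)
    ds.population.to_csv(paths["population"], index=False)
    ds.covariates.to_csv(paths["covariates"], index=False)
    write_neighbor_list(ds.graph, paths["neighbors"])
    ds.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
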