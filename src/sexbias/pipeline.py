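"""End-to-end orchestration: identify -> merge -> characterize -> enrich.

``run_pipeline`` drives the whole analysis from a YAML (or dict) config
and writes plot-data tables plus a run manifest.  Stage order follows
the analysis narrative: per-dataset sex-biased calling, conflict-free
merging into a catalog, chromosomal distribution and clustering,
conservation (group shares and family species counts), tissue
specificity, disease spectrum width, and set enrichment.

All randomness flows from the single config seed via named substreams,
so a rerun with an identical config produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from sexbias import __version__, biasid, enrichment, evoscores, formats, genomeloc
from sexbias.synthdata import SyntheticWorld

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "write_world"]


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{config_path}: config must be a YAML mapping")
    return config


def _check_inputs(config: dict, base: Path) -> None:
    """Fail fast, before any stage runs, if a declared input is missing."""
    paths = []
    for ds in config.get("datasets", []):
        paths += [ds["expr"], ds["meta"]]
    for key in ("annotation", "families", "associations", "tsi", "category_sets"):
        if config.get(key):
            paths.append(config[key])
    missing = [str(p) for p in paths if not (base / p).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")


def _score_comparison_table(catalog, score_map, annotation, score_name):
    try:
        return evoscores.compare_scores(catalog, score_map, annotation, score_name=score_name)
    except ValueError as exc:
        logger.warning("%s comparison skipped: %s", score_name, exc)
        return pd.DataFrame()


def run_pipeline(config, outdir) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    ``config`` is a dict or a YAML path; see the synthetic-world writer
    for the expected keys.  Returns the manifest dict.  Every output
    table is TSV; the catalog and manifest are JSON.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        base = config_path.parent
        config = load_config(config_path)
    else:
        base = Path(config.get("base_dir", "."))
    outdir = Path(outdir)
    _check_inputs(config, base)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "bias").mkdir(exist_ok=True)

    alpha = float(config.get("alpha", 0.05))
    scope = config.get("scope", "group")
    seed = int(config.get("seed", 0))

    # stage 1: per-dataset identification -----------------------------------
    group_map: dict[str, str] = dict(config.get("group_map") or {})
    tissue_map: dict[str, str] = dict(config.get("tissue_map") or {})
    results = []
    dataset_counts = []
    for ds_cfg in config["datasets"]:
        ds_id = ds_cfg.get("id")
        group = group_map.get(ds_id) or biasid.assign_group(ds_id)
        tissue = tissue_map.get(ds_id) or biasid.assign_tissue_class(ds_id)
        dataset = formats.read_expression(
            base / ds_cfg["expr"],
            base / ds_cfg["meta"],
            dataset_id=ds_id,
            disease_group=group,
            tissue_class=tissue,
        )
        group_map[dataset.dataset_id] = group
        result = biasid.identify(dataset, alpha=alpha)
        results.append(result)
        result.table.to_csv(outdir / "bias" / f"{dataset.dataset_id}.tsv", sep="\t", index=False)
        dataset_counts.append(
            {
                "dataset_id": dataset.dataset_id,
                "disease_group": group,
                "tissue_class": tissue,
                "n_female": dataset.n_female,
                "n_male": dataset.n_male,
                "n_tested": result.n_tested,
                "n_fb": len(result.fb),
                "n_mb": len(result.mb),
                "n_dropped_ties": result.n_dropped_ties,
            }
        )

    # stage 2: merge ---------------------------------------------------------
    catalog = biasid.merge(results, group_map, scope=scope)
    catalog_json = {
        "scope": catalog.scope,
        "groups": {
            g: {
                "FB": sorted(catalog.fb(g)),
                "MB": sorted(catalog.mb(g)),
                "excluded_conflicts": sorted(catalog.excluded_conflicts.get(g, set())),
            }
            for g in catalog.group_names
        },
    }
    with open(outdir / "catalog.json", "w") as fh:
        json.dump(catalog_json, fh, indent=2, sort_keys=True)

    ov = biasid.overlap_stats(catalog)
    ov["pairwise_overlap"].to_csv(outdir / "group_overlap_matrix.tsv", sep="\t")

    # stage 3: chromosomal distribution and clustering -----------------------
    annotation = formats.read_gff3(base / config["annotation"])
    chrom_rows = []
    autosome_rows = []
    dist_rows = []
    for group in catalog.group_names:
        sets = {
            "FBmiR": catalog.fb(group),
            "MBmiR": catalog.mb(group),
            "OmiR": catalog.omir(group, annotation.universe),
        }
        for set_name, members in sets.items():
            if members:
                counts = genomeloc.chromosome_counts(members, annotation)
                for chrom, n in counts.items():
                    chrom_rows.append(
                        {"disease_group": group, "set": set_name, "chromosome": chrom, "count": int(n)}
                    )
        biased = sets["FBmiR"] | sets["MBmiR"]
        if biased and not annotation.subset(biased).empty:
            autosome_rows.append(
                {
                    "disease_group": group,
                    "n_biased": len(biased),
                    "autosome_fraction": genomeloc.autosome_fraction(biased, annotation),
                }
            )
        for set_name in ("FBmiR", "MBmiR"):
            try:
                res = genomeloc.compare_distance_distributions(
                    sets[set_name], sets["OmiR"], annotation
                )
            except ValueError as exc:
                logger.warning("%s/%s distance comparison skipped: %s", group, set_name, exc)
                continue
            da = genomeloc.intrachrom_distances(sets[set_name], annotation)
            db = genomeloc.intrachrom_distances(sets["OmiR"], annotation)
            dist_rows.append(
                {
                    "disease_group": group,
                    "comparison": f"{set_name} vs OmiR",
                    "n_pairs_a": len(da),
                    "n_pairs_b": len(db),
                    "median_a_bp": float(pd.Series(da).median()),
                    "median_b_bp": float(pd.Series(db).median()),
                    "u_statistic": res.u_statistic,
                    "p_two_sided": res.p_two_sided,
                }
            )
    pd.DataFrame(chrom_rows).to_csv(outdir / "chromosome_counts.tsv", sep="\t", index=False)
    pd.DataFrame(autosome_rows).to_csv(outdir / "autosome_fraction.tsv", sep="\t", index=False)
    pd.DataFrame(dist_rows).to_csv(outdir / "distance_comparison.tsv", sep="\t", index=False)

    # stage 4: conservation --------------------------------------------------
    cons = evoscores.conservation_proportions(catalog, annotation)
    cons.to_csv(outdir / "conservation_proportions.tsv", sep="\t")

    families = formats.read_mifam(base / config["families"])
    species_scores = evoscores.family_species_count_map(families, annotation.universe)
    fam_table = _score_comparison_table(catalog, species_scores, annotation, "family_species_count")
    fam_table.to_csv(outdir / "family_species_comparison.tsv", sep="\t", index=False)

    # stage 5: tissue specificity -------------------------------------------
    tsi = formats.read_tsi(base / config["tsi"])
    tsi_table = _score_comparison_table(catalog, tsi, annotation, "tsi")
    tsi_table.to_csv(outdir / "tsi_comparison.tsv", sep="\t", index=False)

    # stage 6: disease spectrum width ---------------------------------------
    associations = formats.read_associations(base / config["associations"])
    dsw_scores = {m: evoscores.dsw(m, associations) for m in annotation.universe}
    dsw_table = _score_comparison_table(catalog, dsw_scores, annotation, "dsw")
    dsw_table.to_csv(outdir / "dsw_comparison.tsv", sep="\t", index=False)

    # stage 7: enrichment ----------------------------------------------------
    collections = formats.read_category_sets(base / config["category_sets"])
    enrich_tables = []
    for class_name in sorted(collections):
        coll = collections[class_name]
        for group in catalog.group_names:
            for set_name, members in (("FBmiR", catalog.fb(group)), ("MBmiR", catalog.mb(group))):
                query = members & coll.member_universe
                if not query:
                    logger.info("%s/%s: empty %s query, enrichment skipped", group, set_name, class_name)
                    continue
                table = enrichment.enrich(query, coll)
                table.insert(0, "disease_group", group)
                table.insert(1, "query_set", set_name)
                enrich_tables.append(table)
    enrich_out = (
        pd.concat(enrich_tables, ignore_index=True) if enrich_tables else pd.DataFrame()
    )
    enrich_out.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # manifest ---------------------------------------------------------------
    group_counts = {}
    for group in catalog.group_names:
        fb, mb = catalog.fb(group), catalog.mb(group)
        excluded = catalog.excluded_conflicts.get(group, set())
        group_counts[group] = {
            "n_fb": len(fb),
            "n_mb": len(mb),
            "n_excluded_conflicts": len(excluded),
            "n_identified_total": len(fb | mb | excluded),
        }
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "alpha": alpha,
        "conflict_scope": scope,
        "datasets": dataset_counts,
        "groups": group_counts,
        "overlap": {
            "n_total_union": ov["n_total_union"],
            "n_group_unique": ov["n_group_unique"],
            "pct_group_unique": ov["pct_group_unique"],
        },
        "n_annotated_mirnas": len(annotation),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_world(world: SyntheticWorld, fixtures_dir, seed: int = 0, alpha: float = 0.05) -> Path:
    """Write every artifact of a synthetic world plus a ready-to-run
    pipeline config; returns the config path."""
    fixtures_dir = Path(fixtures_dir)
    fixtures_dir.mkdir(parents=True, exist_ok=True)
    dataset_entries = []
    for ds in world.datasets:
        expr = f"{ds.dataset_id}_expr.tsv"
        meta = f"{ds.dataset_id}_meta.tsv"
        formats.write_expression(ds, fixtures_dir / expr, fixtures_dir / meta)
        world.truths[ds.dataset_id].to_csv(
            fixtures_dir / f"{ds.dataset_id}_truth.tsv", sep="\t", index=False
        )
        dataset_entries.append({"id": ds.dataset_id, "expr": expr, "meta": meta})
    formats.write_gff3(world.annotation, fixtures_dir / "annotation.gff3", world.mature_map)
    formats.write_mifam(world.families, fixtures_dir / "families.mifam.txt")
    formats.write_associations(world.associations, fixtures_dir / "associations.csv")
    formats.write_tsi(world.tsi, fixtures_dir / "tsi.tsv")
    formats.write_category_sets(world.category_sets, fixtures_dir / "category_sets.tsv")
    config = {
        "seed": seed,
        "alpha": alpha,
        "scope": "group",
        "datasets": dataset_entries,
        "group_map": world.group_map,
        "tissue_map": world.tissue_map,
        "annotation": "annotation.gff3",
        "families": "families.mifam.txt",
        "associations": "associations.csv",
        "tsi": "tsi.tsv",
        "category_sets": "category_sets.tsv",
    }
    config_path = fixtures_dir / "run.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
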