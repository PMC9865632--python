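"""End-to-end orchestration from a single TOML config.

The config centralizes every stage's parameters (the survey defaults —
10-kb diversity windows, 5000/500 depth smoothing, the 725-difference
clonemate threshold, MAF 0.03 / missingness 0.10 filtering — are the
defaults here too) and ``run_pipeline`` executes
variants -> popgen -> distances -> depth/CNV -> TE -> pan-genome ->
phenotypes, writing a JSON-lines summary with each stage's parameters
echoed for reproducibility.

A config may either point at existing inputs or set ``[simulate]
enabled = true`` to generate a synthetic fixture first and run on that.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import pandas as pd

from . import depth_cnv, distances, pangenome, phenotypes, popgen, te_quant, variants
from .genotypes import read_vcf
from .io import read_bed, read_bedgraph, read_clade_map, read_fasta, read_te_coverage
from .simulate import PopulationModel, simulate_all
from .te_quant import TELibrary


PATH_KEYS = {"vcf", "clades", "depth_dir", "genes", "ledger", "table", "coverage", "library_fasta"}


def _echo(params: dict) -> dict:
    """Stage parameters for the summary, excluding file paths."""
    return {k: v for k, v in params.items() if k not in PATH_KEYS}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


DEFAULTS = {
    "variants": {"max_missing_fraction": 0.10, "min_maf": 0.03},
    "popgen": {"window": 10_000, "ld_max_dist": 10_000},
    "distances": {"clonemate_threshold": 725, "gap_quantile": 0.5},
    "cnv": {"window": 5000, "step": 500, "min_ratio": 1.25, "min_len": 10_000, "merge_gap": 1},
    "te": {"outlier_fraction_pct": 2.0},
    "pangenome": {"min_breadth": 0.2, "min_depth": 1.0, "novel_min_length": 500},
    "phenotypes": {"exclude": []},
}


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    merged = {k: dict(v) for k, v in DEFAULTS.items()}
    for section, values in cfg.items():
        if isinstance(values, dict):
            merged.setdefault(section, {}).update(values)
        else:
            merged[section] = values
    return merged


def validate_config(path) -> list[str]:
    """Range- and cross-checks without touching data. Empty list means ok."""
    try:
        cfg = load_config(path)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        return [f"config unparsable: {exc}"]
    v: list[str] = []
    var = cfg["variants"]
    if not 0 <= var["max_missing_fraction"] <= 1:
        v.append("variants.max_missing_fraction must lie in [0, 1]")
    if not 0 <= var["min_maf"] <= 1:
        v.append("variants.min_maf must lie in [0, 1]")
    if cfg["popgen"]["window"] <= 0:
        v.append("popgen.window must be positive")
    if cfg["popgen"]["ld_max_dist"] <= 0:
        v.append("popgen.ld_max_dist must be positive")
    if cfg["distances"]["clonemate_threshold"] <= 0:
        v.append("distances.clonemate_threshold must be positive")
    cnv = cfg["cnv"]
    if not cnv["window"] >= cnv["step"] > 0:
        v.append("cnv window/step must satisfy window >= step > 0")
    if cnv["min_ratio"] <= 1:
        v.append("cnv.min_ratio must exceed 1")
    if cnv["min_len"] <= 0:
        v.append("cnv.min_len must be positive")
    pg = cfg["pangenome"]
    if not 0 <= pg["min_breadth"] <= 1:
        v.append("pangenome.min_breadth must lie in [0, 1]")
    simulate_on = cfg.get("simulate", {}).get("enabled", False)
    if not simulate_on:
        for section, key in (("variants", "vcf"), ("cnv", "depth_dir"), ("pangenome", "genes")):
            p = cfg.get(section, {}).get(key)
            if p is not None and not Path(p).exists():
                v.append(f"{section}.{key}: path {p} does not exist")
    return v


def _model_from_config(sim_cfg: dict, seed: int) -> PopulationModel:
    kwargs = {
        k: v
        for k, v in sim_cfg.items()
        if k not in ("enabled",) and k in PopulationModel.__dataclass_fields__
    }
    kwargs.setdefault("seed", seed)
    if "strains_per_clade" in kwargs:
        kwargs["strains_per_clade"] = tuple(kwargs["strains_per_clade"])
    return PopulationModel(**kwargs)


def run_pipeline(config_path, out_dir=None) -> dict:
    """Run every configured stage; returns the summary dict also written
    to ``summary.jsonl`` (one JSON object per stage, parameters echoed)."""
    problems = validate_config(config_path)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out", "haplopop_out"))
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}

    sim_cfg = cfg.get("simulate", {})
    if sim_cfg.get("enabled", False):
        model = _model_from_config(sim_cfg, seed)
        fixture = out / "fixture"
        try:
            simulate_all(model, fixture)
        except Exception as exc:
            raise PipelineError(f"stage simulate failed: {exc}") from exc
        cfg["variants"].setdefault("vcf", str(fixture / "population.vcf"))
        cfg["popgen"].setdefault("clades", str(fixture / "clades.tsv"))
        cfg["cnv"].setdefault("depth_dir", str(fixture / "depth"))
        cfg["pangenome"].setdefault("genes", str(fixture / "genes.bed"))
        chrom_lengths = {c: model.chrom_length for c in model.chrom_names}
        summary["simulate"] = {"params": {"seed": seed, "n_strains": len(model.strain_names())}}
    else:
        chrom_lengths = None

    # ---- variants ------------------------------------------------------
    var_cfg = cfg["variants"]
    vcf_path = var_cfg.get("vcf")
    if vcf_path is None:
        raise PipelineError("stage variants failed: no VCF configured")
    try:
        m = read_vcf(vcf_path)
        summary_cls = variants.classify_variants(m)
        fcfg = variants.FilterConfig(var_cfg["max_missing_fraction"], var_cfg["min_maf"])
        filtered = variants.filter_snps(m, fcfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage variants failed on {vcf_path}: {exc}") from exc
    summary["variants"] = {
        "params": _echo(var_cfg),
        "n_total": summary_cls.n_total,
        "n_snp": summary_cls.n_snp,
        "n_indel": summary_cls.n_indel,
        "n_singleton": summary_cls.n_singleton,
        "ts_tv": summary_cls.ts_tv_ratio,
        "n_filtered_snps": filtered.n_sites,
    }

    # ---- popgen --------------------------------------------------------
    pg_cfg = cfg["popgen"]
    try:
        table, genome_pi, _ = popgen.nucleotide_diversity(
            filtered, pg_cfg["window"], chrom_lengths
        )
        table.to_csv(out / "pi_windows.tsv", sep="\t", index=False)
        ld = popgen.ld_decay(filtered, pg_cfg["ld_max_dist"])
        ld.table.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        stage = {
            "params": _echo(pg_cfg),
            "genome_pi": genome_pi,
            "ld_half": ld.ld_half,
        }
        clades_path = pg_cfg.get("clades")
        if clades_path:
            clade_of = read_clade_map(clades_path)
            clades = sorted(set(clade_of.values()))
            fsts = {}
            for i, a in enumerate(clades):
                for b in clades[i + 1 :]:
                    pa = [s for s in filtered.strains if clade_of.get(s) == a]
                    pb = [s for s in filtered.strains if clade_of.get(s) == b]
                    if len(pa) >= 2 and len(pb) >= 2:
                        _, g = popgen.fst(filtered, pa, pb, pg_cfg["window"], chrom_lengths)
                        fsts[f"{a}|{b}"] = g
            stage["fst"] = fsts
        summary["popgen"] = stage
    except Exception as exc:
        raise PipelineError(f"stage popgen failed: {exc}") from exc

    # ---- distances -----------------------------------------------------
    d_cfg = cfg["distances"]
    try:
        dmat = distances.pairwise_distances(filtered)
        dmat.to_frame().to_csv(out / "distances.tsv", sep="\t")
        gap = distances.distance_gap(dmat, d_cfg["gap_quantile"])
        groups = distances.clonal_groups(dmat, d_cfg["clonemate_threshold"])
        summary["distances"] = {
            "params": _echo(d_cfg),
            "gap": gap,
            "n_groups": groups.n_groups,
            "n_clonemate_strains": groups.n_clonemate_strains,
        }
    except Exception as exc:
        raise PipelineError(f"stage distances failed: {exc}") from exc

    # ---- depth / CNV ---------------------------------------------------
    cnv_cfg = cfg["cnv"]
    depth_dir = cnv_cfg.get("depth_dir")
    genes_path = cfg["pangenome"].get("genes")
    genes = read_bed(genes_path) if genes_path else []
    if depth_dir and Path(depth_dir).is_dir():
        try:
            seg_rows = []
            tracks = {}
            for bg in sorted(Path(depth_dir).glob("*.bedgraph")):
                strain = bg.stem
                track = depth_cnv.DepthTrack(read_bedgraph(bg))
                tracks[strain] = track
                log2, _ = depth_cnv.normalize_log2(track)
                smoothed = depth_cnv.smooth(log2, cnv_cfg["window"], cnv_cfg["step"])
                segs = depth_cnv.call_duplications(
                    smoothed, cnv_cfg["min_ratio"], cnv_cfg["min_len"], cnv_cfg["merge_gap"]
                )
                depth_cnv.genes_in_segments(segs, genes)
                for s in segs:
                    seg_rows.append(
                        (strain, s.chrom, s.start, s.end, s.copy_number, len(s.genes))
                    )
            pd.DataFrame(
                seg_rows, columns=["strain", "chrom", "start", "end", "copy_number", "n_genes"]
            ).to_csv(out / "duplications.tsv", sep="\t", index=False)
            summary["cnv"] = {
                "params": _echo(cnv_cfg),
                "n_segments": len(seg_rows),
            }
        except Exception as exc:
            raise PipelineError(f"stage cnv failed: {exc}") from exc

        # ---- pan-genome (reuses the depth tracks) ----------------------
        if genes:
            try:
                pa = pangenome.gene_presence(
                    tracks, genes, cfg["pangenome"]["min_breadth"], cfg["pangenome"]["min_depth"]
                )
                ledger_path = cfg["pangenome"].get("ledger")
                ledger = (
                    pangenome.read_novel_gene_ledger(
                        ledger_path, cfg["pangenome"]["novel_min_length"]
                    )
                    if ledger_path
                    else None
                )
                acct = pangenome.core_pan_accounting(pa, ledger)
                pa.presence.to_csv(out / "presence_absence.tsv", sep="\t")
                summary["pangenome"] = {
                    "params": _echo(cfg["pangenome"]),
                    "n_reference": acct.n_reference_genes,
                    "n_dispensable": acct.n_dispensable,
                    "n_core": acct.n_core,
                    "n_novel": acct.n_novel,
                    "n_pan": acct.n_pan,
                }
            except Exception as exc:
                raise PipelineError(f"stage pangenome failed: {exc}") from exc

    # ---- TE ------------------------------------------------------------
    te_cfg = cfg["te"]
    if te_cfg.get("coverage"):
        try:
            cov = read_te_coverage(te_cfg["coverage"])
            library = TELibrary.from_sequences(read_fasta(te_cfg["library_fasta"]))
            abundances = []
            for strain, grp in cov.groupby("strain"):
                abundances.append(
                    te_quant.te_abundance(
                        str(strain),
                        dict(zip(grp["te"], grp["mean_depth"])),
                        te_cfg["genome_mean_depth"],
                        library,
                        te_cfg["genome_length"],
                    )
                )
            per_el, per_strain = te_quant.te_summary(
                abundances, te_cfg["outlier_fraction_pct"]
            )
            per_strain.to_csv(out / "te_fractions.tsv", sep="\t")
            summary["te"] = {
                "params": _echo(te_cfg),
                "fraction_range_pct": [
                    float(per_strain["genome_fraction_pct"].min()),
                    float(per_strain["genome_fraction_pct"].max()),
                ],
            }
        except Exception as exc:
            raise PipelineError(f"stage te failed: {exc}") from exc

    # ---- phenotypes ----------------------------------------------------
    ph_cfg = cfg["phenotypes"]
    if ph_cfg.get("table"):
        try:
            traits = pd.read_csv(ph_cfg["table"], index_col=0)
            screen = phenotypes.condition_screen(traits, ph_cfg["exclude"])
            screen.to_csv(out / "trait_cv.tsv", sep="\t")
            summary["phenotypes"] = {
                "params": {"exclude": list(ph_cfg["exclude"])},
                "n_conditions": int(len(screen)),
                "top_cv": float(screen["cv"].iloc[0]) if len(screen) else None,
            }
        except Exception as exc:
            raise PipelineError(f"stage phenotypes failed: {exc}") from exc

    with open(out / "summary.jsonl", "w") as fh:
        for stage_name, payload in summary.items():
            fh.write(json.dumps({"stage": stage_name, **payload}, sort_keys=True) + "\n")
    return summary
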