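"""End-to-end orchestration: cohort -> copy number -> CNV -> alleles -> stats -> MDS.

The pipeline runs either fully synthetic (reference and cohort generated from
the built-in study conditions) or from user-supplied tables (allele FASTA,
coverage TSV, metadata TSV, polymorphism JSON). All randomness derives from
one root seed; every output directory gets a config echo, a config hash and a
stage log, and a rerun with the same config is bit-identical for the
deterministic stages. Loaded-coverage runs stop after the CNV stage (allele
calling needs per-segment reads, which only the synthetic path provides).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alleles as al
from . import cnv as cnvmod
from . import coverage as covmod
from . import datasets, mds, popgen, simulate
from .reference_db import AlleleDatabase, group_operational_segments, load_allele_fasta


@dataclass
class PipelineConfig:
    locus: str = "TRBV"
    out_dir: str = "vgenepop_out"
    seed: int = 0
    allele_fasta: str | None = None  # None -> built-in synthetic reference
    coverage_tsv: str | None = None  # None -> simulate a cohort
    metadata_tsv: str | None = None
    polymorphisms_json: str | None = None  # None -> built-in definitions
    identity_threshold: float = 0.95
    min_individuals: int = 2
    alpha: float = 0.01
    coverage_noise_cv: float = 0.05
    n_individuals_per_region: dict | None = None
    depth_per_copy: float = 12.0
    error_rate: float = 0.002
    two_copy_min_fraction: float = 0.95
    exclude_groups: list = field(default_factory=list)  # anomalous-coverage blocklist

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    db: AlleleDatabase
    metadata: pd.DataFrame
    cn_table: pd.DataFrame
    cnv_callsets: dict
    relative_abundance: dict
    r_squared: pd.DataFrame | None
    regional_tests: dict
    set_difference: tuple | None
    allele_table: pd.DataFrame | None
    calls: list | None
    snp_table: pd.DataFrame | None
    summary: dict
    embedding: mds.Embedding | None
    separation: float | None
    stages: list


def load_polymorphisms(path: str | Path) -> list:
    with open(path) as fh:
        return [cnvmod.CnvPolymorphism.from_dict(d) for d in json.load(fh)]


def write_polymorphisms(polys: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in polys], fh, indent=1)


def _write_tsv(frame: pd.DataFrame, path: Path, written: list) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; on error, partial outputs are removed and the
    failing stage is named."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: list[dict] = []
    state: dict = {}

    def stage(name, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})

    def setup():
        for attr in ("allele_fasta", "coverage_tsv", "metadata_tsv",
                     "polymorphisms_json"):
            p = getattr(config, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if config.allele_fasta:
            db = load_allele_fasta(config.allele_fasta, config.locus)
        else:
            db = datasets.synthetic_reference(config.locus, seed=config.seed)
        group_operational_segments(db, config.identity_threshold)
        if config.polymorphisms_json:
            polys = load_polymorphisms(config.polymorphisms_json)
        else:
            polys = datasets.study_polymorphisms(config.locus)
        state["db"], state["polys"] = db, polys
        if config.coverage_tsv:
            state["coverage"] = pd.read_csv(config.coverage_tsv, sep="\t")
            state["metadata"] = pd.read_csv(config.metadata_tsv, sep="\t")
            state["cohort"] = None
        else:
            sim_cfg = datasets.study_config(
                config.locus, db, seed=config.seed,
                n_individuals_per_region=config.n_individuals_per_region,
                coverage_noise_cv=config.coverage_noise_cv)
            cohort = simulate.simulate_population(sim_cfg, db)
            state["cohort"] = cohort
            state["coverage"] = cohort.coverage
            state["metadata"] = cohort.metadata

    def select():
        selected = simulate.select_cohort(state["metadata"], config.locus)
        state["selected"] = selected
        keep = set(selected["individual_id"])
        state["coverage"] = state["coverage"][
            state["coverage"]["individual_id"].isin(keep)]
        _write_tsv(selected, out / "metadata.tsv", written)

    def copy_number():
        cn = covmod.copy_number_table(state["coverage"])
        cn = cn[~cn["group_id"].isin(config.exclude_groups)]
        state["cn_table"] = cn
        state["cn_matrix"] = covmod.cn_matrix(cn)
        _write_tsv(cn, out / "cn.tsv", written)

    def cnv_calls():
        mat = state["cn_matrix"]
        callsets, ra, tests = {}, {}, {}
        regions = state["selected"].set_index("individual_id")["region"]
        call_rows = []
        for poly in state["polys"]:
            if any(g not in mat.columns for g in poly.group_ids):
                warnings.warn(f"{poly.polymorphism_id}: groups missing; skipped")
                continue
            cs = cnvmod.cluster_copy_numbers(mat, poly)
            callsets[poly.polymorphism_id] = cs
            ra[poly.polymorphism_id] = cnvmod.variant_relative_abundance(cs)
            tests[poly.polymorphism_id] = cnvmod.regional_distribution_test(
                cs, regions, config.alpha)
            df = cs.calls.copy()
            df.insert(0, "polymorphism_id", poly.polymorphism_id)
            call_rows.append(df)
        state["cnv_callsets"], state["ra"], state["tests"] = callsets, ra, tests
        poly_groups = [p.group_ids for p in state["polys"]]
        state["r2"] = (cnvmod.pairwise_r_squared(mat)
                       if len(mat) >= 3 else None)
        # presence sets from called CN (two-copy groups always present)
        presence = {}
        for ind in mat.index:
            present = set(mat.columns)
            for pid, cs in callsets.items():
                row = cs.calls[cs.calls["individual_id"] == ind]
                if len(row) == 0:
                    continue
                for g in cs.polymorphism.group_ids:
                    if int(row.iloc[0][f"cn_{g}"]) == 0:
                        present.discard(g)
            presence[ind] = present
        state["set_diff"] = (cnvmod.segment_set_difference_probability(
            presence, stratify_by=regions) if len(presence) >= 2 else None)
        if call_rows:
            _write_tsv(pd.concat(call_rows, ignore_index=True),
                       out / "cnv_calls.tsv", written)
            _write_tsv(pd.concat(
                [s.rename("relative_abundance").reset_index().assign(
                    polymorphism_id=pid) for pid, s in ra.items()],
                ignore_index=True), out / "relative_abundance.tsv", written)
        if state["r2"] is not None:
            state["r2"].to_csv(out / "r_squared.tsv", sep="\t",
                               float_format="%.6g")
            written.append(out / "r_squared.tsv")
        state["poly_groups"] = poly_groups

    def allele_stage():
        cohort = state["cohort"]
        state["allele_table"] = state["calls"] = state["snps"] = None
        if cohort is None:
            return  # no reads available for loaded coverage tables
        db = state["db"]
        two_copy = covmod.flag_two_copy_groups(state["cn_matrix"],
                                               config.two_copy_min_fraction)
        with_alleles = sorted(set(two_copy)
                              & set(cohort.config.allele_freqs[next(
                                  iter(cohort.config.allele_freqs))]))
        keep = set(state["selected"]["individual_id"])
        rng = np.random.default_rng(config.seed + 1)
        phased = []
        n_ambiguous = 0
        for geno in cohort.genotypes:
            if geno.individual_id not in keep:
                continue
            for gid in with_alleles:
                reads = simulate.simulate_segment_reads(
                    geno, gid, db, read_length=cohort.config.read_length,
                    depth_per_copy=config.depth_per_copy,
                    error_rate=config.error_rate, rng=rng)
                ref = db.group_by_id(gid).representative_seq
                try:
                    phased.append(al.phase_segment_reads(
                        reads, ref, individual_id=geno.individual_id,
                        group_id=gid))
                except al.AmbiguityError:
                    n_ambiguous += 1
        table, calls = al.call_alleles_cohort(
            phased, db, min_individuals=config.min_individuals,
            two_copy_groups=with_alleles,
            regions=state["selected"].set_index("individual_id")["region"])
        state["allele_table"], state["calls"] = table, calls
        state["snps"] = al.identify_snps(calls, db, config.min_individuals)
        state["two_copy"] = with_alleles
        state["n_ambiguous"] = n_ambiguous
        _write_tsv(table, out / "alleles.tsv", written)
        _write_tsv(al.calls_to_frame(calls), out / "calls.tsv", written)
        _write_tsv(state["snps"], out / "snps.tsv", written)

    def stats_stage():
        summary: dict = {}
        table, calls = state["allele_table"], state["calls"]
        if table is not None and len(table):
            db = state["db"]
            seqs: dict = {}
            for c in calls:
                if c.called:
                    seqs.setdefault(c.group_id, {})[c.allele_name] = \
                        al.apply_mutations(db.get(c.base_allele).nt_seq,
                                           c.mutations)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                div = popgen.diversity_summary(table, seqs, state["snps"],
                                               state["two_copy"])
            regions = state["selected"].set_index("individual_id")["region"]
            hap_rows = pd.DataFrame(
                [{"region": regions[c.individual_id], "locus": c.group_id,
                  "allele": c.allele_name}
                 for c in calls if c.called and c.individual_id in regions.index])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fst = popgen.fst_weir_cockerham(hap_rows)
            priv_al = popgen.private_alleles(calls, regions)
            priv_snv = popgen.private_snvs(state["snps"], calls, db, regions)
            summary.update({
                "avg_pairwise_bp_diff_pct": div.avg_pairwise_bp_diff_pct,
                "avg_snps_per_segment": div.avg_snps_per_segment,
                "novel_alleles": div.novel_count,
                "total_alleles": div.total_count,
                "novel_fraction": div.novel_fraction,
                "fst_overall": fst.overall,
                "n_private_alleles": len(priv_al),
                "n_private_snvs": len(priv_snv),
            })
            priv = pd.DataFrame([vars(v) for v in priv_al + priv_snv])
            _write_tsv(priv, out / "private_variants.tsv", written)
            counts = table.groupby("group_id")["allele_name"].nunique()
            summary["allele_counts_per_segment"] = counts.to_dict()
        if state.get("set_diff") is not None:
            overall, per_region = state["set_diff"]
            summary["p_segment_sets_differ"] = overall
        state["summary"] = summary
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
        written.append(out / "summary.json")

    def mds_stage():
        state["embedding"] = state["separation"] = None
        calls = state["calls"]
        if calls is None:
            return
        matrix = mds.allele_copy_matrix(calls)
        if len(matrix) < 3:
            return
        emb = mds.mds_embed(matrix, dims=2, seed=config.seed + 2)
        regions = state["selected"].set_index("individual_id")["region"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sep = mds.region_separation_score(emb, regions)
        state["embedding"], state["separation"] = emb, sep
        coords = emb.coordinates.copy()
        coords.insert(0, "region", regions.loc[coords.index])
        coords.insert(0, "individual_id", coords.index)
        coords["stress"] = emb.stress
        _write_tsv(coords.reset_index(drop=True), out / "mds.tsv", written)

    stage("setup", setup)
    stage("select_cohort", select)
    stage("copy_number", copy_number)
    stage("cnv_calls", cnv_calls)
    stage("alleles", allele_stage)
    stage("stats", stats_stage)
    stage("mds", mds_stage)

    log = {"seed": config.seed, "config_hash": config.config_hash(),
           "config": asdict(config), "stages": stages}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)

    return PipelineResult(
        config=config, db=state["db"], metadata=state["selected"],
        cn_table=state["cn_table"], cnv_callsets=state["cnv_callsets"],
        relative_abundance=state["ra"], r_squared=state["r2"],
        regional_tests=state["tests"], set_difference=state.get("set_diff"),
        allele_table=state["allele_table"], calls=state["calls"],
        snp_table=state["snps"], summary=state["summary"],
        embedding=state["embedding"], separation=state["separation"],
        stages=stages)
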