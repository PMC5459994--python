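"""Readers, writers, run configuration and the end-to-end pipeline.

All tables travel as headered TSV; locus annotations as 6-column BED (0-based,
half-open, strand in column 6, the score column carrying the functional flag);
reads as BED-like TSV with a trailing column of comma-separated ``pos:base``
SNP observations.  Every file this module writes is re-parseable by its own
reader.  ``run_pipeline`` chains simulate -> assign -> call -> model ->
profiles -> repertoire, logging stage-tagged lines to stderr and writing a
JSON manifest with the resolved configuration, seed, and a hash of every
output, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation_model import (
    ActivationModelParams,
    categories_from_calls,
    category_probs,
    estimate_params,
    expected_active_fraction,
    goodness_of_fit,
)
from .allelic_assignment import ReadPairInterval, assign_reads
from .clonal_profiles import (
    build_ratio_matrix,
    cluster_profiles,
    pca_profiles,
    plot_ratio_heatmap,
)
from .monoallelic_calling import call_with_replicates, split_by_sample
from .repertoire import (
    ncrna_repertoire_correlation,
    normalize_repertoire,
    rearrangement_allelic_ratio,
)
from .synthetic_data import (
    CountNoiseParams,
    Locus,
    SnpRecord,
    VSegment,
    make_locus,
    make_snps,
    simulate_clone,
    simulate_counts,
    simulate_pool,
    simulate_reads,
    simulate_repertoire,
)

logger = logging.getLogger("allelochoice")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


# ---------------------------------------------------------------- formats

def write_bed(segments, path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            score = 1 if s.functional else 0
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.id}\t{score}\t{s.strand}\n")


def read_bed(path) -> list[VSegment]:
    """Parse a 6-column BED locus annotation; malformed lines are rejected by number."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start_i >= end_i or start_i < 0:
                raise FormatError(f"{path}:{lineno}: need 0 <= start < end")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: missing or invalid strand column")
            segments.append(
                VSegment(id=name, chrom=chrom, start=start_i, end=end_i, strand=strand,
                         functional=score != "0")
            )
    return segments


def write_counts(table: pd.DataFrame, path) -> None:
    table[["feature_id", "sample", "b6", "cast"]].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Read an allele count table (feature_id, sample, b6, cast) with validation."""
    t = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "sample": str})
    required = ["feature_id", "sample", "b6", "cast"]
    if list(t.columns[:4]) != required:
        raise FormatError(f"{path}: expected header {' '.join(required)}")
    for col in ("b6", "cast"):
        vals = t[col]
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError(f"{path}: non-integer counts in column {col!r}")
        if (vals < 0).any():
            raise FormatError(f"{path}: negative counts in column {col!r}")
    if t.duplicated(subset=["feature_id", "sample"]).any():
        raise FormatError(f"{path}: duplicate (feature_id, sample) rows")
    return t


def write_snps(snps, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tb6_base\tcast_base\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.b6_base}\t{s.cast_base}\n")


def read_snps(path) -> list[SnpRecord]:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(t.columns) != ["chrom", "pos", "b6_base", "cast_base"]:
        raise FormatError(f"{path}: expected header chrom pos b6_base cast_base")
    return [
        SnpRecord(chrom=r.chrom, pos=int(r.pos), b6_base=r.b6_base, cast_base=r.cast_base)
        for r in t.itertuples()
    ]


def write_reads(reads, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            obs = ",".join(f"{pos}:{base}" for pos, base in r.snp_observations) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\t{obs}\n")


def read_reads(path) -> list[ReadPairInterval]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            chrom, start, end, _name, _score, strand, obs = fields[:7]
            observations = ()
            if obs != ".":
                observations = tuple(
                    (int(p.split(":")[0]), p.split(":")[1]) for p in obs.split(",")
                )
            reads.append(
                ReadPairInterval(chrom=chrom, start=int(start), end=int(end), strand=strand,
                                 snp_observations=observations)
            )
    return reads


def write_repertoire(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("v_id", "allele", "count", "percent", "percent_library") if c in table]
    table[cols].to_csv(path, sep="\t", index=False)


def read_repertoire(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"v_id": str, "allele": str})
    if list(t.columns[:3]) != ["v_id", "allele", "count"]:
        raise FormatError(f"{path}: expected header v_id allele count ...")
    return t


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id", na_values="NA")


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Resolved parameters of an end-to-end run (embedded in every manifest)."""

    seed: int = 0
    n_total: int = 96
    n_potential: int = 60
    p_b6: float = 0.43
    p_cast: float = 0.25
    n_clones: int = 4
    mu_active: float = 100.0
    mu_leak: float = 1.0
    dispersion: float = 0.1
    n_replicates: int = 2
    pool_clones: int = 50
    alpha: float = 0.05
    fold_min: float = 2.0
    min_depth_call: int = 20
    min_depth_heatmap: int = 10
    coupling: float = 0.9
    early_allele: str = "B6"
    time_fraction: float = 1.0
    repertoire_depth: int = 100_000
    heatmap: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @property
    def model_params(self) -> ActivationModelParams:
        return ActivationModelParams(self.p_b6, self.p_cast, self.n_potential, self.n_total)

    @property
    def noise(self) -> CountNoiseParams:
        return CountNoiseParams(self.mu_active, self.mu_leak, self.dispersion, self.n_replicates)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


PRESETS = {
    # per-allele activation probabilities and potential/total segment counts of
    # the hybrid pre-B-cell study conditions
    "study": {"p_b6": 0.43, "p_cast": 0.25, "n_potential": 60, "n_total": 96},
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    root = logging.getLogger("allelochoice")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full synthetic-to-analysis pipeline and write a JSON manifest.

    Stages: simulate (locus, SNPs, per-clone replicate counts, pool, reads for
    the first clone) -> assign (haplotype-tag and window-assign the simulated
    reads) -> call (replicate-consistent monoallelic calls per clone, reading
    the counts back from disk) -> model (category tallies, per-allele
    activation probability estimates, goodness of fit) -> profiles (ratio
    matrix, PCA, dendrogram, heatmap) -> repertoire (per-clone rearrangement
    repertoires, ncRNA coupling correlation).  Any stage failure aborts with
    the stage name.  All randomness derives from ``config.seed``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        written.append(path)
        return path

    ss = np.random.SeedSequence(config.seed)
    (locus_ss, snp_ss, clones_ss, pool_ss, reads_ss, rep_ss) = ss.spawn(6)

    stage = "simulate"
    try:
        logger.info("stage %s: locus of %d segments (%d potential), %d clones",
                    stage, config.n_total, config.n_potential, config.n_clones)
        locus = make_locus(config.n_total, config.n_potential, locus_ss)
        snps = make_snps(locus, seed=snp_ss)
        clone_seeds = clones_ss.spawn(2 * config.n_clones)
        clones = []
        tables = []
        for i in range(config.n_clones):
            clone = simulate_clone(locus, config.model_params, clone_seeds[2 * i],
                                   clone_id=f"clone{i + 1}")
            clones.append(clone)
            tables.append(simulate_counts(clone, config.noise, seed=clone_seeds[2 * i + 1]))
        pool = simulate_pool(locus, config.model_params, config.pool_clones, config.noise,
                             seed=pool_ss)
        counts = pd.concat(tables + [pool], ignore_index=True)
        reads = simulate_reads(clones[0], locus, snps, config.noise, seed=reads_ss)
        emit("locus.bed", write_bed, locus.segments)
        (out / "potential_set.txt").write_text(
            "\n".join(sorted(locus.potential_set)) + "\n"
        )
        written.append(out / "potential_set.txt")
        emit("snps.tsv", write_snps, snps)
        emit("counts.tsv", write_counts, counts)
        emit("reads.tsv", write_reads, reads)
        manifest["stages"][stage] = {
            "n_segments": len(locus),
            "n_snps": len(snps),
            "n_reads": len(reads),
        }
    except Exception as e:  # noqa: BLE001 - stage context is the contract
        raise PipelineError(stage, str(e)) from e

    stage = "assign"
    try:
        logger.info("stage %s: %d read pairs", stage, len(reads))
        assigned, tallies = assign_reads(reads, locus, snps, sample=f"{clones[0].clone_id}_assigned")
        emit("assigned_counts.tsv", write_counts, assigned)
        manifest["stages"][stage] = tallies
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "call"
    try:
        counts_back = read_counts(out / "counts.tsv")
        calls_by_clone = {}
        for clone in clones:
            sub = counts_back[counts_back["sample"].str.startswith(f"{clone.clone_id}_rep")]
            reps = split_by_sample(sub)
            calls = call_with_replicates(reps, config.alpha, config.fold_min,
                                         config.min_depth_call)
            calls_by_clone[clone.clone_id] = calls
            path = out / f"calls_{clone.clone_id}.tsv"
            calls.to_csv(path, sep="\t", index=False, na_rep="NA")
            written.append(path)
        manifest["stages"][stage] = {
            clone_id: {k: int(v) for k, v in calls["category"].value_counts().items()}
            for clone_id, calls in calls_by_clone.items()
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, f"{out / 'counts.tsv'}: {e}") from e

    stage = "model"
    try:
        model_report = {}
        for clone_id, calls in calls_by_clone.items():
            tally = categories_from_calls(calls, n_potential=config.n_potential)
            est = estimate_params(tally, n_potential=config.n_potential, n_total=config.n_total)
            gof = goodness_of_fit(tally, est.params, n_fitted=2)
            model_report[clone_id] = {
                "categories": {
                    "silent": tally.silent, "mono_b6": tally.mono_b6,
                    "mono_cast": tally.mono_cast, "biallelic": tally.biallelic,
                },
                "p_b6": est.params.p_b6, "p_cast": est.params.p_cast,
                "se_b6": est.se_b6, "se_cast": est.se_cast,
                "gof_stat": gof.statistic, "gof_df": gof.df, "gof_p": gof.p_value,
            }
        model_report["expected_active_fraction"] = expected_active_fraction(config.model_params)
        model_report["category_probs"] = {
            view: category_probs(config.model_params)[view].to_dict()
            for view in ("potential", "marginal")
        }
        path = out / "model.json"
        path.write_text(json.dumps(model_report, indent=2, sort_keys=True) + "\n")
        written.append(path)
        manifest["stages"][stage] = {"clones": list(calls_by_clone)}
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "profiles"
    try:
        matrix = build_ratio_matrix(counts, min_depth=config.min_depth_heatmap)
        emit("ratio_matrix.tsv", write_matrix, matrix)
        pca = pca_profiles(matrix)
        path = out / "pca.tsv"
        pca_out = pca.coordinates.copy()
        pca_out.to_csv(path, sep="\t", index_label="sample")
        written.append(path)
        clustering = cluster_profiles(matrix)
        path = out / "dendrogram.nwk"
        path.write_text(clustering.newick + "\n")
        written.append(path)
        if config.heatmap:
            plot_ratio_heatmap(matrix, out / "heatmap.png")
            written.append(out / "heatmap.png")
        manifest["stages"][stage] = {
            "n_features": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "pc1_var": float(pca.explained_variance_ratio[0]),
        }
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "repertoire"
    try:
        rep_seeds = rep_ss.spawn(config.n_clones)
        correlations = {}
        for i, clone in enumerate(clones):
            ncrna = tables[i]
            rep = simulate_repertoire(
                clone, ncrna, coupling=config.coupling, early_allele=config.early_allele,
                time_fraction=config.time_fraction, n_events=config.repertoire_depth,
                seed=rep_seeds[i],
            )
            rep = normalize_repertoire(rep)
            emit(f"repertoire_{clone.clone_id}.tsv", write_repertoire, rep)
            ncrna_pooled = ncrna.groupby("feature_id")[["b6", "cast"]].sum().reset_index()
            ncrna_ratio = pd.Series(
                [  # same depth convention as the calls
                    b / (b + c) if b + c >= config.min_depth_call else np.nan
                    for b, c in zip(ncrna_pooled["b6"], ncrna_pooled["cast"])
                ],
                index=ncrna_pooled["feature_id"],
            )
            rr = rearrangement_allelic_ratio(rep, min_depth=config.min_depth_call)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                r, p, n = ncrna_repertoire_correlation(ncrna_ratio, rr)
            if np.isnan(r):  # degenerate: one allele had no active segment
                correlations[clone.clone_id] = {"pearson_r": None, "p": None, "n": n}
            else:
                correlations[clone.clone_id] = {"pearson_r": r, "p": p, "n": n}
        path = out / "correlation.json"
        path.write_text(json.dumps(correlations, indent=2, sort_keys=True) + "\n")
        written.append(path)
        manifest["stages"][stage] = correlations
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d outputs in %s", len(written), out)
    return manifest
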