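"""End-to-end orchestration: FASTA in, seven analysis tables out.

``run_analysis`` reads and validates a CDS FASTA, computes every per-gene
and pooled statistic, and writes stable TSV tables (per-gene indices, RSCU,
neutrality fit, ENC plot, PR2 plot, correlation matrices, optimal codons).
Each table opens with a single ``#`` metadata line (version, config hash,
input digest) so a run can be reproduced bit-exactly. ``run_simulate``
writes a synthetic gene set plus its ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .composition import profile_frame
from .evolution import correlation_matrix, enc_plot, neutrality_fit, pr2_frame, pr2_summary
from .genetic_code import STANDARD_CODE
from .optimal import delta_rscu_report, optimal_codons, select_extreme_sets, write_optimal_tsv
from .sequences import (
    SKIP_INVALID,
    CodingSequence,
    CodonCountTable,
    ValidationPolicy,
    count_codons,
    pool_counts,
    read_cds_fasta,
    write_cds_fasta,
)
from .simulate import SyntheticConfig, generate
from .usage import gene_usage_indices, rscu, write_rscu_tsv

logger = logging.getLogger(__name__)

CORRELATION_COLUMNS = ["t3s", "c3s", "a3s", "g3s", "gc3s", "gc1", "gc2", "gc3", "gc", "cai", "enc"]


@dataclass
class AnalysisReport:
    """Paths to the seven output tables plus headline results."""

    out_dir: Path
    tables: Dict[str, Path]
    n_genes: int
    n_records: int
    gene_indices: pd.DataFrame
    rscu_table: pd.DataFrame
    neutrality: "object"
    enc_plot_summary: Dict[str, float]
    pr2_means: Dict[str, float]
    optimal: List[str]
    metadata: Dict[str, str]


def _metadata_line(metadata: Dict[str, str]) -> str:
    return "# " + " ".join(f"{k}={v}" for k, v in metadata.items()) + "\n"


def _write_with_header(path: Path, metadata: Dict[str, str], writer) -> None:
    tmp = path.with_suffix(path.suffix + ".body")
    writer(tmp)
    with open(path, "w") as out, open(tmp) as body:
        out.write(_metadata_line(metadata))
        out.write(body.read())
    tmp.unlink()


def read_reference_counts(path: str | Path) -> CodonCountTable:
    """Read an external codon usage table (TSV with `codon` and `count` columns)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"codon", "count"}.issubset(df.columns):
        raise ValueError(f"{path}: reference table needs 'codon' and 'count' columns")
    return CodonCountTable(dict(zip(df["codon"], df["count"])))


def run_analysis(
    cds_path: str | Path,
    out_dir: str | Path,
    policy: ValidationPolicy = SKIP_INVALID,
    cai_reference: Optional[CodonCountTable] = None,
    extreme_fraction: float = 0.05,
    x3s_convention: str = "simple",
    pr2_method: str = "per_gene",
) -> AnalysisReport:
    """Run the full codon-usage-bias analysis on a CDS FASTA."""
    cds_path, out_dir = Path(cds_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    raw = cds_path.read_bytes()
    n_records = sum(1 for line in raw.decode(errors="replace").splitlines() if line.startswith(">"))
    sequences = read_cds_fasta(cds_path, policy=policy)
    logger.info("analyzing %d/%d genes from %s", len(sequences), n_records, cds_path)

    gene_counts = {s.gene_id: count_codons(s) for s in sequences}
    profiles = profile_frame(sequences, convention=x3s_convention)
    usage_df = gene_usage_indices(
        gene_counts, cai_reference=cai_reference, extreme_fraction=extreme_fraction
    )
    gene_indices = profiles.join(usage_df)

    pooled = pool_counts(list(gene_counts.values()))
    rscu_table = rscu(pooled, include_stops=True)

    fit = neutrality_fit(gene_indices["gc3"], gene_indices["gc12"])
    enc_records, enc_summary, enc_hist = enc_plot(gene_indices)
    pr2_points = pr2_frame(gene_counts)
    pr2_means = pr2_summary(pr2_points, method=pr2_method)

    high_ids, low_ids = select_extreme_sets(gene_indices["enc"], fraction=extreme_fraction)
    high_pool = pool_counts([gene_counts[g] for g in high_ids])
    low_pool = pool_counts([gene_counts[g] for g in low_ids])
    opt_report = delta_rscu_report(high_pool, low_pool)
    opt = optimal_codons(opt_report)

    config = {
        "extreme_fraction": extreme_fraction,
        "x3s_convention": x3s_convention,
        "pr2_method": pr2_method,
        "policy": policy.on_invalid,
        "max_ambiguous_fraction": policy.max_ambiguous_fraction,
        "external_cai_reference": cai_reference is not None,
    }
    metadata = {
        "codonbias": __version__,
        "input_sha256": hashlib.sha256(raw).hexdigest()[:16],
        "config_sha256": hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16],
        "n_genes": str(len(sequences)),
    }

    tables: Dict[str, Path] = {}

    def table(name: str, writer) -> None:
        path = out_dir / f"{name}.tsv"
        _write_with_header(path, metadata, writer)
        tables[name] = path

    table("gene_indices", lambda p: gene_indices.to_csv(p, sep="\t", float_format="%.4f"))
    table("rscu", lambda p: write_rscu_tsv(rscu_table, p))

    def write_neutrality(p: Path) -> None:
        pd.DataFrame(
            [{
                "slope": fit.slope, "intercept": fit.intercept, "pearson_r": fit.pearson_r,
                "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
                "interpretation": fit.interpretation(),
            }]
        ).to_csv(p, sep="\t", index=False, float_format="%.4g")

    table("neutrality", write_neutrality)

    def write_enc_plot(p: Path) -> None:
        with open(p, "w") as fh:
            for k, v in enc_summary.items():
                fh.write(f"# {k}={v:.4f}\n" if isinstance(v, float) else f"# {k}={v}\n")
            enc_records.to_csv(fh, sep="\t", float_format="%.4f")
            fh.write("# histogram of rel_deviation\n")
            enc_hist.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    table("enc_plot", write_enc_plot)

    def write_pr2(p: Path) -> None:
        with open(p, "w") as fh:
            for k, v in pr2_means.items():
                fh.write(f"# {k}={v:.4f}\n")
            pr2_points.to_csv(fh, sep="\t", float_format="%.4f")

    table("pr2", write_pr2)

    def write_corr(p: Path) -> None:
        corr = correlation_matrix(gene_indices[CORRELATION_COLUMNS])
        with open(p, "w") as fh:
            fh.write("# pearson_r\n")
            corr.r.to_csv(fh, sep="\t", float_format="%.3f")
            fh.write("# p_value\n")
            corr.p.to_csv(fh, sep="\t", float_format="%.3g")
            fh.write("# flags (* p<0.05, ** p<0.01)\n")
            corr.flags.to_csv(fh, sep="\t")

    table("correlations", write_corr)

    def write_opt(p: Path) -> None:
        with open(p, "w") as fh:
            fh.write(f"# high_expression_set={','.join(high_ids)}\n")
            fh.write(f"# low_expression_set={','.join(low_ids)}\n")
            fh.write(f"# optimal_codons={','.join(opt) if opt else 'none'}\n")
        tmp = p.with_suffix(".part")
        write_optimal_tsv(opt_report, tmp)
        with open(p, "a") as fh, open(tmp) as body:
            fh.write(body.read())
        tmp.unlink()

    table("optimal_codons", write_opt)

    logger.info(
        "mean GC %.4f | mean ENC %.2f | neutrality slope %.3f (R2 %.3f) | optimal codons: %s",
        gene_indices["gc"].mean(), gene_indices["enc"].mean(), fit.slope, fit.r_squared,
        ", ".join(opt) if opt else "none",
    )
    return AnalysisReport(
        out_dir=out_dir,
        tables=tables,
        n_genes=len(sequences),
        n_records=n_records,
        gene_indices=gene_indices,
        rscu_table=rscu_table,
        neutrality=fit,
        enc_plot_summary=enc_summary,
        pr2_means=pr2_means,
        optimal=opt,
        metadata=metadata,
    )


def run_simulate(config: SyntheticConfig, out_dir: str | Path) -> Dict[str, Path]:
    """Generate a synthetic CDS set and write FASTA + ground-truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences, truth = generate(config)
    fasta = out_dir / "synthetic.fasta"
    truth_path = out_dir / "ground_truth.tsv"
    write_cds_fasta(sequences, fasta)
    with open(truth_path, "w") as fh:
        fh.write(f"# codonbias={__version__} seed={config.seed} regime={config.regime} "
                 f"config_sha256={config.digest()}\n")
        truth.to_csv(fh, sep="\t", float_format="%.6f")
    logger.info("wrote %d synthetic genes to %s", len(sequences), fasta)
    return {"fasta": fasta, "ground_truth": truth_path}
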