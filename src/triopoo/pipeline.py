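"""End-to-end per-SNP parent-of-origin analysis and report writing.

``run_analysis`` produces one row per configured SNP with the raw p-value
and odds ratio of each term (imprinting alpha; maternal-genotype beta and
gamma) and a Bonferroni flag computed within user-declared analysis
families.  Raw p-values are always reported; the Bonferroni family size is
the number of SNPs in the row's family (optionally SNP x term pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import loglinear, trio_data

__all__ = [
    "AnalysisResultRow",
    "load_snp_config",
    "run_analysis",
    "rows_to_frame",
    "write_report",
    "merge_ped_data",
]

_TERMS = loglinear.TERMS


@dataclass
class AnalysisResultRow:
    snp_id: str
    gene: str
    risk_allele: str | None
    analysis_family: str
    n_trios: int = 0
    n_informative_trios: int = 0
    n_excluded_missing: int = 0
    n_mendel_errors: int = 0
    #: per term: {'status': 'ok'|'inestimable'|'missing-data',
    #:            'p_value': float|None, 'odds_ratio': float|None,
    #:            'bonferroni_significant': bool|None}
    terms: dict[str, dict] = field(default_factory=dict)
    notes: str = ""


def load_snp_config(path: str | Path) -> pd.DataFrame:
    """Read the risk-allele configuration TSV.

    Required columns: snp_id, risk_allele.  Optional: analysis_family
    (defaults to 'all'), gene (defaults to the SNP id).
    """
    # keep_default_na=False: gene symbols like "NULL" or "NA" are real names
    cfg = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"snp_id", "risk_allele"} - set(cfg.columns)
    if missing:
        raise ValueError(f"snp config lacks required columns: {sorted(missing)}")
    if cfg["snp_id"].duplicated().any():
        dups = cfg.loc[cfg["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate SNP ids in config: {dups}")
    if "analysis_family" not in cfg.columns:
        cfg["analysis_family"] = "all"
    if "gene" not in cfg.columns:
        cfg["gene"] = cfg["snp_id"]
    cfg["analysis_family"] = cfg["analysis_family"].replace("", "all")
    cfg.loc[cfg["gene"] == "", "gene"] = cfg["snp_id"]
    return cfg


def _informative_count(table: trio_data.CellTable) -> int:
    # Cells 1 (2x2 mating) and 15 (0x0) are absorbed entirely by their own
    # stratum intercepts and contribute to no term.
    return int(table.counts[1:14].sum())


def run_analysis(
    individuals: Sequence[trio_data.Individual],
    snp_map: trio_data.SnpMap,
    snp_config: pd.DataFrame,
    level: float = 0.05,
    spec: loglinear.ModelSpec | None = None,
    baseline: Literal["joint", "single"] = "joint",
    tests_per_family: Literal["snps", "snp_terms"] = "snps",
) -> list[AnalysisResultRow]:
    """Per-SNP term tests with Bonferroni correction within analysis families.

    The dataset is expected to have passed :func:`triopoo.trio_data.apply_qc`.
    A SNP listed in the config but absent from the dataset yields a
    'missing-data' row rather than aborting the run.
    """
    spec = spec or loglinear.ModelSpec()
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    trios, _ = trio_data.build_trios(individuals)
    family_sizes = snp_config.groupby("analysis_family")["snp_id"].count().to_dict()

    rows: list[AnalysisResultRow] = []
    for rec in snp_config.itertuples(index=False):
        row = AnalysisResultRow(
            snp_id=rec.snp_id,
            gene=rec.gene,
            risk_allele=rec.risk_allele,
            analysis_family=rec.analysis_family,
        )
        if rec.snp_id not in snp_map:
            row.notes = "missing-data"
            row.terms = {
                t: {"status": "missing-data", "p_value": None,
                    "odds_ratio": None, "bonferroni_significant": None}
                for t in _TERMS
            }
            rows.append(row)
            continue
        table = trio_data.tabulate(trios, rec.snp_id, snp_map, rec.risk_allele)
        row.n_trios = table.n_trios
        row.n_informative_trios = _informative_count(table)
        row.n_excluded_missing = table.n_excluded_missing
        row.n_mendel_errors = table.n_mendel_errors

        n_tests = family_sizes[rec.analysis_family]
        if tests_per_family == "snp_terms":
            n_tests *= len(spec.terms)

        if table.n_complete == 0:
            row.notes = "uninformative"
            row.terms = {
                t: {"status": "inestimable", "p_value": None,
                    "odds_ratio": None, "bonferroni_significant": None}
                for t in _TERMS
            }
            rows.append(row)
            continue

        results = loglinear.test_all_terms(table, spec, baseline=baseline)
        for t in _TERMS:
            tt = results.get(t)
            if tt is None or tt.status != "ok":
                row.terms[t] = {
                    "status": "inestimable",
                    "p_value": None,
                    "odds_ratio": None,
                    "bonferroni_significant": None,
                }
            else:
                row.terms[t] = {
                    "status": "ok",
                    "p_value": tt.p_value,
                    "odds_ratio": tt.odds_ratio,
                    "bonferroni_significant": tt.p_value * n_tests <= level,
                }
        if all(v["status"] != "ok" for v in row.terms.values()):
            row.notes = "uninformative"
        rows.append(row)
    return rows


_COLUMNS = [
    "snp_id", "gene", "risk_allele", "analysis_family",
    "n_trios", "n_informative_trios", "n_excluded_missing", "n_mendel_errors",
    "p_alpha", "or_alpha", "p_beta", "or_beta", "p_gamma", "or_gamma",
    "sig_alpha", "sig_beta", "sig_gamma", "notes",
]


def rows_to_frame(rows: Sequence[AnalysisResultRow]) -> pd.DataFrame:
    data = []
    for r in rows:
        rec: dict = {
            "snp_id": r.snp_id,
            "gene": r.gene,
            "risk_allele": r.risk_allele,
            "analysis_family": r.analysis_family,
            "n_trios": r.n_trios,
            "n_informative_trios": r.n_informative_trios,
            "n_excluded_missing": r.n_excluded_missing,
            "n_mendel_errors": r.n_mendel_errors,
            "notes": r.notes,
        }
        for short, term in (("alpha", "alpha"), ("beta", "beta"), ("gamma", "gamma")):
            info = r.terms.get(term, {})
            rec[f"p_{short}"] = info.get("p_value")
            rec[f"or_{short}"] = info.get("odds_ratio")
            rec[f"sig_{short}"] = info.get("bonferroni_significant")
        data.append(rec)
    return pd.DataFrame(data, columns=_COLUMNS)


def _fmt_p(p: float | None) -> str:
    if p is None:
        return "N/A"
    return f"{p:.2g}" if p < 0.995 else "1.0"


def _fmt_or(v: float | None) -> str:
    return "N/A" if v is None else f"{v:.1f}"


def write_report(
    rows: Sequence[AnalysisResultRow],
    path: str | Path,
    format: Literal["tsv", "markdown"] = "tsv",
) -> None:
    """Write the analysis report.

    TSV keeps full numeric precision; the markdown view mirrors the
    published table layout (SNP, Gene, RA, then p/OR per term) with odds
    ratios to one decimal, p-values to two significant figures, and
    inestimable terms rendered as ``N/A``.
    """
    if not rows:
        raise ValueError("no rows to report")
    path = Path(path)
    if format == "tsv":
        # repr() gives the shortest exactly round-trippable decimal form
        rows_to_frame(rows).to_csv(
            path, sep="\t", index=False, float_format=lambda v: repr(float(v))
        )
        return
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    header = [
        "SNP", "Gene", "RA",
        "p-α", "OR-α", "p-ß", "OR-ß", "p-γ", "OR-γ", "Notes",
    ]
    lines = [
        "| " + " | ".join(header) + " |",
        "|" + "|".join("---" for _ in header) + "|",
    ]
    for r in rows:
        cells = [r.snp_id, r.gene, r.risk_allele or "N/A"]
        for term in _TERMS:
            info = r.terms.get(term, {})
            cells.append(_fmt_p(info.get("p_value")))
            cells.append(_fmt_or(info.get("odds_ratio")))
        cells.append(r.notes)
        lines.append("| " + " | ".join(cells) + " |")
    path.write_text("\n".join(lines) + "\n")


def merge_ped_data(datasets: Sequence[trio_data.PedData]) -> trio_data.PedData:
    """Pool cohorts genotyped on the same SNP map (e.g. CD + UC trios)."""
    if not datasets:
        raise ValueError("nothing to merge")
    ref = [s.snp_id for s in datasets[0].snp_map]
    individuals = list(datasets[0].individuals)
    warnings_ = list(datasets[0].warnings)
    for other in datasets[1:]:
        if [s.snp_id for s in other.snp_map] != ref:
            raise ValueError("cannot merge datasets with different SNP maps")
        individuals.extend(other.individuals)
        warnings_.extend(other.warnings)
    keys = [(ind.family_id, ind.individual_id) for ind in individuals]
    if len(set(keys)) != len(keys):
        raise ValueError("merged datasets share family/individual ids")
    return trio_data.PedData(
        individuals=individuals,
        snp_map=datasets[0].snp_map,
        warnings=warnings_,
    )
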