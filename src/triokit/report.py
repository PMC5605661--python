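"""End-to-end reproduction of the fixture statistics as one structured report.

`run_report` rebuilds the per-domain tally from the packaged mutation list,
verifies it against the packaged expected matrix, computes enrichment
scores, the whole-gene and DH1 Poisson hotspot tests, and the ddG
classification summary, and (optionally) writes the results as TSV + JSON
with a provenance manifest (fixture checksums and parameter values).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import datasets
from .catalog import enrichment_score, tally_mutations, write_tally
from .ddg import classify_ddg, count_disruptive, star_mismatches
from .enrichment import (
    GENOME_WIDE_THRESHOLD,
    hotspot_test,
    mutation_rate_per_base,
    poisson_upper_tail,
    rescale_expected,
)

__all__ = ["run_report", "FixtureIntegrityError"]

#: Cohort size pooled over the source de novo studies and the matching
#: expected whole-gene de novo count under the background mutational model.
DEFAULT_N_INDIVIDUALS = 4890
DEFAULT_LAMBDA_GENE = 1.07

#: DH1 de novo event count credited by the primary subdomain test.  The raw
#: tally credits 8 case events to DH1 (6 missense + truncation + CNV); the
#: published subdomain test used 7.  Both are reported.
DH1_PRIMARY_K = 7


class FixtureIntegrityError(RuntimeError):
    """Raised when the packaged mutation list no longer reproduces the
    packaged expected tally."""


def run_report(
    out_dir: str | Path | None = None,
    n_individuals: int = DEFAULT_N_INDIVIDUALS,
    lambda_gene: float = DEFAULT_LAMBDA_GENE,
    threshold: float = GENOME_WIDE_THRESHOLD,
    mutations=None,
    gene=None,
) -> dict:
    """Compute the full fixture-statistics report; optionally write it.

    Returns a dict with the tally (DataFrame), enrichment scores, hotspot
    results, ddG summary and manifest.  ``mutations``/``gene`` may override
    the packaged fixtures (integrity checking then being skipped).
    """
    using_fixtures = mutations is None and gene is None
    gene = gene or datasets.load_trio_gene_model()
    mutations = mutations if mutations is not None else datasets.load_trio_mutations()

    tally = tally_mutations(mutations, gene)
    if using_fixtures:
        expected = datasets.load_expected_tally()
        if not tally.to_frame().equals(expected.to_frame()):
            raise FixtureIntegrityError(
                "packaged mutation list does not reproduce the packaged tally"
            )

    scores = enrichment_score(tally)
    k_gene = tally.grand_total("total_case")
    gene_p = poisson_upper_tail(k_gene, lambda_gene)

    domain_results = hotspot_test(tally, gene, lambda_gene, threshold)
    dh1 = gene.domain("DH1")
    lambda_dh1 = rescale_expected(lambda_gene, dh1.length_aa, gene.protein_length_aa)
    dh1_primary_p = poisson_upper_tail(DH1_PRIMARY_K, lambda_dh1)

    ddg_records = datasets.load_ddg_table()
    ddg_summary = {
        "n_records": len(ddg_records),
        "n_missense": sum(r.mclass == "missense" for r in ddg_records),
        "disruptive_missense": count_disruptive(ddg_records, restrict_to="missense"),
        "interface_eliminated": sum(
            classify_ddg(r) == "interface_eliminated" for r in ddg_records
        ),
        "star_mismatches": star_mismatches(ddg_records),
    }

    report = {
        "gene": gene.gene_symbol,
        "tally": tally.to_frame(),
        "enrichment": scores,
        "whole_gene": {
            "k_observed": k_gene,
            "lambda": lambda_gene,
            "n_individuals": n_individuals,
            "p_value": gene_p,
            "significant": gene_p < threshold,
        },
        "domains": [
            {
                "domain": r.domain,
                "k": r.k_observed,
                "lambda": r.lambda_domain,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in domain_results
        ],
        "dh1_primary": {
            "k_observed": DH1_PRIMARY_K,
            "lambda": lambda_dh1,
            "p_value": dh1_primary_p,
            "significant": dh1_primary_p < threshold,
            "rate_per_base_per_individual": mutation_rate_per_base(
                DH1_PRIMARY_K, dh1.length_aa, n_individuals
            ),
        },
        "ddg": ddg_summary,
        "manifest": {
            "fixture_checksums": datasets.fixture_checksums() if using_fixtures else {},
            "parameters": {
                "n_individuals": n_individuals,
                "lambda_gene": lambda_gene,
                "threshold": threshold,
            },
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tally(tally, out_dir / "domain_tally.tsv")
        scores.to_frame().to_csv(out_dir / "enrichment_scores.tsv", sep="\t")
        pd.DataFrame(report["domains"]).to_csv(
            out_dir / "hotspot_results.tsv", sep="\t", index=False
        )
        serializable = {
            k: v for k, v in report.items() if k not in ("tally", "enrichment")
        }
        (out_dir / "report.json").write_text(json.dumps(serializable, indent=2))
    return report
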