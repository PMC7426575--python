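"""Integration recipe against the deposited cohorts (not run in CI).

This module is intentionally NOT collected by pytest (its name lacks the
``test_`` prefix): it documents how to benchmark the pipeline against the
deposited data, which requires a network download and the full 546-gene
registry file, neither of which is available in the offline test
environment.

Recipe
------
1. Download the discovery-cohort expression matrix from NCBI GEO accession
   GSE110907 (99 never-smoker lung adenocarcinomas) and the melanoma
   validation cohort from GSE93157 (18 ICB-treated patients, PanCancer
   immune panel), e.g. with GEOparse or the GEO supplementary-file FTP.
2. Export the expression matrices to the package's TSV dialect
   (gene_id + one column per sample, linear-scale values).
3. Obtain the full 8-panel registry file (gene<TAB>panel<TAB>tag, 546
   genes) and pass it via ``--panels``.
4. Run the pipeline and compare against the reported reference values.

Expected outcomes when run on the deposited data:
- ``immunecycle cluster --expression GSE110907.tsv --panels registry.tsv``
  should yield subgroup sizes close to 37 / 15 / 47 with phenotype labels
  "UB+ IFN1p- AP-", "UB- IFN1s- AP-", "UB+ IFN1+ AP+".
- subgroup-2 mean TMB from the matched exome calls should be close to
  2.644 mutations/Mb (subgroups 1 and 3 near 1.919 and 1.700).
- ``immunecycle tic-irp`` on GSE93157 with its response labels should
  give a TIC/IRP Pearson correlation near 0.52 with 4 of 6 responders in
  quadrant 1.
"""

from pathlib import Path

import immunecycle as ic


def run_discovery_benchmark(expression_tsv: Path, registry_tsv: Path) -> None:
    """Cluster a downloaded discovery-cohort matrix over the full registry."""
    model = ic.ImmuneSubgroupModel.from_files(expression_tsv, registry_tsv, k=3)
    results = model.fit()
    print(results.summary())


def run_validation_benchmark(expression_tsv: Path, response_tsv: Path) -> None:
    """TIC/IRP scoring of a downloaded ICB-treated validation cohort."""
    expr = ic.read_expression(expression_tsv)
    response = ic.read_response(response_tsv)
    results = ic.TicIrpModel(expr, response=response).fit()
    print(results.summary())


if __name__ == "__main__":
    import sys
    if len(sys.argv) != 3:
        sys.exit("usage: python integration_gse110907.py "
                 "<expression.tsv> <registry.tsv>")
    run_discovery_benchmark(Path(sys.argv[1]), Path(sys.argv[2]))
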