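#!/usr/bin/env python
"""Optional validation of driver-score / missense-label concordance on the
public score downloads.

This check needs two externally downloaded tables (neither is bundled and
no download is attempted here):

* a driver-score table (gene, tumour type, chrom, pos, ref, alt, score),
  as distributed with the saturation-mutagenesis driver-score release;
* a missense-prediction table (chrom, pos, ref, alt, score, class),
  gzip-transparent, in the public missense-pathogenicity release dialect.

The two releases are built on different genome assemblies; lifting the
coordinates onto a common assembly before joining is the caller's
responsibility. Variants are joined on (chrom, pos, ref, alt) with
upper-cased alleles, labels are binarised benign vs non-benign, and
per-gene precision-recall AUCs (averaged over tumour types) are written
alongside the overall and panel-restricted means.

    python scripts/validate_external.py --scores boostdm.tsv \
        --labels AlphaMissense.tsv.gz --out concordance.tsv
"""

from __future__ import annotations

import argparse
import gzip
import json
from pathlib import Path

import pandas as pd

from crcgerm.concordance import ScoredVariantPair, per_gene_auc, summarize_concordance
from crcgerm.tables import load_panel, packaged_panel


def _read_table(path: Path, names: dict[str, str]) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df = df.rename(columns=names)
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    return df


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("--scores", type=Path, required=True, help="driver-score TSV")
    parser.add_argument("--labels", type=Path, required=True, help="missense-prediction TSV(.gz)")
    parser.add_argument("--panel", type=Path, default=None, help="gene panel TSV (default: packaged)")
    parser.add_argument("--policy", default="nonbenign_positive")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    scores = _read_table(
        args.scores,
        {"CHROM": "chrom", "POS": "pos", "REF": "ref", "ALT": "alt",
         "gene": "gene", "cancer_type_annotations": "tumor_type",
         "boostDM_score": "score"},
    )
    labels = _read_table(
        args.labels,
        {"#CHROM": "chrom", "POS": "pos", "REF": "ref", "ALT": "alt",
         "am_pathogenicity": "label_score", "am_class": "label_class"},
    )
    joined = scores.merge(labels, on=["chrom", "pos", "ref", "alt"], how="inner")
    pairs = [
        ScoredVariantPair(str(r.gene), str(r.tumor_type), float(r.score), str(r.label_class))
        for r in joined.itertuples()
    ]
    panel = load_panel(args.panel) if args.panel else packaged_panel()
    aucs = per_gene_auc(pairs, policy=args.policy)
    summary = summarize_concordance(aucs, panel)
    pd.DataFrame(sorted(aucs.items()), columns=["gene", "auc"]).to_csv(
        args.out, sep="\t", index=False
    )
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
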