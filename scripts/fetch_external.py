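#!/usr/bin/env python
"""Fetch the public real datasets used by the reanalysis pipelines.

Convenience script, not part of the tested surface: it needs network
access.  It downloads the companion data repository of the analyses
(github.com/abichat/correlationtree_analysis) into data/external/raw/ and
explains which files to export.

The reanalysis entry points (cortree.evaluate.reanalyze and the acceptance
check on the Chlamydiae excerpt) expect, under data/external/:

    chlamydiae_counts.tsv     taxa x samples integer counts (21 x 26)
    chlamydiae_groups.tsv     two columns: sample id, environment label
    chlamydiae_phylogeny.nwk  newick phylogeny over the 21 OTUs

The Chlamydiae excerpt is also distributed with the structSSI R package
(`data(chlamydiae)`); exporting from either source works.
"""

import sys
import tarfile
import urllib.request
from pathlib import Path

REPO_TARBALL = (
    "https://github.com/abichat/correlationtree_analysis/archive/refs/heads/master.tar.gz"
)


def main() -> None:
    dest = Path(__file__).resolve().parent.parent / "data" / "external"
    raw = dest / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    tarball = raw / "correlationtree_analysis.tar.gz"
    print(f"downloading {REPO_TARBALL} ...")
    try:
        urllib.request.urlretrieve(REPO_TARBALL, tarball)
    except OSError as exc:
        sys.exit(f"download failed ({exc}); network access is required")
    with tarfile.open(tarball) as tf:
        tf.extractall(raw)
    print(f"extracted into {raw}")
    print(__doc__)


if __name__ == "__main__":
    main()
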