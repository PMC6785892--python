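"""The full benchmark pipeline on a generated corpus.

Generates the standard synthetic corpus (planted antigen families,
CDR groups, epitope conformers, MHC G-domains and quality defects), runs
the four branches with default thresholds, and prints the stage counts
and the non-redundant benchmark table for the Ab-Ag branch.
"""

import json
import tempfile
from pathlib import Path

from immunobench import FilterConfig, load_manifest, make_corpus, run_all

workdir = Path(tempfile.mkdtemp())
manifest = make_corpus(workdir / "corpus", profile="standard", seed=42)
records, refs, _ = load_manifest(manifest)
print(f"loaded {len(records)} complexes")

result = run_all(records, FilterConfig(), refs)
print(json.dumps(result["summary"]["ab_ag"], indent=1, sort_keys=True))

table = result["tables"]["ab_ag"]
print("\nAb-Ag benchmark rows (one line per kept complex):")
print(table[["structure_id", "antigen_cluster", "receptor_cluster",
             "epitope_cluster", "pair_cluster_id",
             "is_representative"]].to_string(index=False))
print("\n-> 16 complexes survive the quality filters and collapse to"
      f" {table['pair_cluster_id'].nunique()} distinct receptor-epitope"
      " pairs; one representative (best resolution) is flagged per pair.")
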