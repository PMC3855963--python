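"""Gene-level analysis of the four epigenetic regulators (external data).

The published analysis covers ASXL1, EZH2, DNMT3A and TET2 with 314
curated substitutions.  Those inputs are not redistributable with this
package; supply them yourself:

* ``data/external/wild_types.fasta`` — UniProt canonical sequences
  Q8IXJ9 (ASXL1), Q15910 (EZH2), Q9Y6K1 (DNMT3A), Q6N021 (TET2), with the
  gene symbols as record identifiers;
* ``data/external/variants.tsv`` — the curated substitutions, columns
  ``gene``, ``substitution`` (X123Y form), ``label`` (SNP or MUT).

The conserved-domain intervals for these genes ship with the package.
Expected outcome: 314 variants (194 MUT + 120 SNP), 159 of them outside
conserved domains (108 SNP + 51 MUT), and per-gene classifier
frequencies F(0.476), F(0.411), F(0.071) and F(0.491).
"""

from pathlib import Path

import ismvar as iv
from ismvar.reproduction import selection_table

external = Path(__file__).resolve().parent.parent / "data" / "external"
fasta = external / "wild_types.fasta"
table = external / "variants.tsv"

if not (fasta.exists() and table.exists()):
    raise SystemExit(
        f"external inputs missing.\nExpected:\n  {fasta}\n  {table}\n"
        "See this script's docstring for what to place there."
    )

result = iv.run_study(fasta, table, subset=iv.NCFD)
print(result.summary.to_string(), end="\n\n")
print(selection_table(result).to_string(index=False), end="\n\n")
print("evaluation on the subset outside conserved domains:")
for metric, value in result.evaluation.to_dict().items():
    print(f"  {metric}: {'undefined' if value is None else f'{value:.4g}'}")
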