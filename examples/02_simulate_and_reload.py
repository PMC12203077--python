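"""Write a simulated dataset to standard formats and read it back.

The generator emits Matrix Market counts plus TSV metadata — the same
formats the I/O layer ingests — so a full write → read → test round trip
works without any binary intermediates.
"""

import tempfile
from pathlib import Path

import pandas as pd

from discde import attach_individuals, generate_dataset, read_counts, write_dataset

ds = generate_dataset(n_genes=100, n_individuals=8, n_cell=50, fold=1.3, seed=7)

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    write_dataset(ds, out)
    print("wrote:", sorted(p.name for p in out.iterdir()))

    cm = read_counts(out / "matrix.mtx", out / "genes.txt", out / "cells.txt")
    cm = attach_individuals(cm, pd.read_csv(out / "cell_meta.tsv", sep="\t"))
    identical = (cm.counts != ds.counts.counts).nnz == 0
    print(f"reloaded {cm.n_genes} genes × {cm.n_cells} cells; "
          f"counts identical to the generated matrix: {identical}")
    print("cells per individual:", cm.cells_per_individual().to_dict())
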