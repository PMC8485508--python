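"""Feature-table quality filtering and rarefaction.

Discards samples with fewer than 10,000 reads and rarefies the remainder
to a common depth of 15,000 reads, the depth at which presence/absence and
diversity become comparable across samples.  Writes the rarefied table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gutshift import io
from gutshift.preprocess import filter_samples, rarefy
from gutshift.studies import derive_seed

SEED = 0
BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    counts = io.load_feature_table(BASE / "inputs" / "counts.tsv")
    filtered = filter_samples(counts, min_reads=10_000)
    rarefied = rarefy(filtered, depth=15_000, seed=derive_seed(SEED, "rarefy"))
    io.write_feature_table(rarefied, BASE / "rarefied_counts.tsv")
    print(f"samples: {counts.n_samples} input -> {filtered.n_samples} with "
          f">= 10,000 reads -> {rarefied.n_samples} rarefied to 15,000")
    assert (rarefied.sample_sums() == 15_000).all()
    print(f"wrote {BASE / 'rarefied_counts.tsv'}")


if __name__ == "__main__":
    main()
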