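"""Clean the occurrence table and derive one age interval per species.

Applies the standard curation chain — drop records above species rank, drop
very imprecise stratigraphic intervals, drop taxa whose ages come from the
(higher-resolution) morphology dataset — then randomly subsamples one
occurrence per remaining species for its age interval.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from fbdstrata.compare import _seeds
from fbdstrata.occurrences import (clean_occurrences, one_occurrence_per_species,
                                   read_occurrences)


def main() -> None:
    syn = RESULTS / "synthetic"
    out = RESULTS / "cleaned"
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(SEED + 1, 2)

    occ = read_occurrences(syn / "occurrences.csv")
    morph = set((syn / "morph_taxa.txt").read_text().split())
    kept, audit = clean_occurrences(occ, max_interval_myr=15.0, exclude=morph)
    print(f"cleaning {len(occ)} occurrence records: kept {len(kept)}; "
          f"dropped {audit['rank']} above species rank, "
          f"{audit['imprecise']} imprecise (>15 myr), "
          f"{audit['excluded']} already in the morphology set")

    ages = one_occurrence_per_species(kept, seed=seeds[0])
    print(f"occurrence-only species with one sampled age interval: {len(ages)}")
    ages.to_csv(out / "occurrence_only_ages.csv")
    with open(out / "cleaning_audit.json", "w") as fh:
        json.dump({"input_records": len(occ), "retained": len(kept),
                   "audit": audit, "n_species": len(ages)},
                  fh, indent=2, sort_keys=True)
    print(f"wrote cleaned ages and audit to {out}")


if __name__ == "__main__":
    main()
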