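"""Simulate the synthetic study clade.

Draws one constant-rate FBD realization (the "truth"), assigns genus-level
monophyletic groupings, emits the fossil occurrence table with stage-binned
age intervals, the biased morphology taxon subset, a character matrix at the
classic morphological-matrix scale, and the genus constraint bundle.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, study_config

from fbdstrata.compare import _seeds
from fbdstrata.occurrences import one_occurrence_per_species, write_occurrences
from fbdstrata.simulate import (FBDParams, Timescale, assign_genera,
                                bin_occurrence_ages, select_morph_taxa,
                                simulate_characters, simulate_fbd)
from fbdstrata.trees import export_constraints, write_trees


def main() -> None:
    out = RESULTS / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    syn = study_config()["synthetic"]
    seeds = _seeds(SEED, 8)

    params = FBDParams(seed=seeds[0], **syn["fbd"])
    history, recon, occ = simulate_fbd(params)
    print(f"simulated clade: {recon.tree.n_tips()} sampled species, "
          f"{len(occ)} fossil occurrences, root age {recon.tree.root_age} Ma")

    genus_map = assign_genera(history, syn["tau_genus"])
    occ["genus"] = occ["taxon"].map(genus_map)
    n_genera = len(set(genus_map.values()))
    print(f"genus horizon {syn['tau_genus']} Ma -> {n_genera} monophyletic genera")

    scale = Timescale.uniform(params.t_origin, syn["n_stages"])
    binned = bin_occurrence_ages(occ, scale, p_coarse=syn["p_coarse"],
                                 seed=seeds[1])
    ages = one_occurrence_per_species(binned, seed=seeds[2])
    morph = select_morph_taxa(occ, k=syn["n_morph"], beta=syn["beta"],
                              seed=seeds[3])
    print(f"morphology subset: {len(morph)} of {len(ages)} species "
          f"(abundance bias beta={syn['beta']})")

    chars = simulate_characters(recon, n_chars=254, n_states=3,
                                missing_frac=0.3, seed=seeds[4])
    chars.loc[sorted(morph)].to_csv(out / "characters.csv")

    write_trees(recon.tree, out / "true_tree.nwk")
    write_occurrences(binned, out / "occurrences.csv")
    ages.to_csv(out / "taxon_ages.csv")
    (out / "morph_taxa.txt").write_text("\n".join(morph) + "\n")

    # constraints require a morphology-bearing anchor per genus; genera the
    # biased subset missed cannot be constrained and are reported instead
    covered = {g for t, g in genus_map.items() if t in set(morph)}
    constrained = {t: g for t, g in genus_map.items() if g in covered}
    skipped = sorted(set(genus_map.values()) - covered)
    if skipped:
        print(f"{len(skipped)} genera have no morphology-bearing member and "
              "get no constraint:", ", ".join(skipped))
    export_constraints(constrained, ages,
                       morph_taxa=morph,
                       nexus_path=out / "constraints.nex",
                       json_path=out / "constraints.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": SEED, "fbd": syn["fbd"], "tau_genus": syn["tau_genus"],
                   "n_stages": syn["n_stages"], "p_coarse": syn["p_coarse"],
                   "n_morph": syn["n_morph"], "beta": syn["beta"],
                   "n_sampled_species": recon.tree.n_tips(),
                   "n_occurrences": len(occ), "n_genera": n_genera},
                  fh, indent=2, sort_keys=True)
    print(f"wrote tree, occurrences, ages, characters and constraints to {out}")


if __name__ == "__main__":
    main()
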