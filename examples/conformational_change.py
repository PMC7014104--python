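"""Representative-structure selection and per-residue conformational change.

Simulates an ensemble of a toy peptide (a pure-water stand-in) and a second
ensemble whose residue-3 side chain is swung by 60 degrees (a cosolvent
stand-in), picks each ensemble's medoid representative, and measures the
per-residue heavy-atom RMSD between the two representatives after backbone
superposition.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from allosite.conformation import per_residue_rmsd, select_representative
from allosite.synthetic import gen_perturbed_family, make_toy_structure

base = make_toy_structure(8)

# swing residue 3's side chain (CB, CG) about its CA by 60 degrees
coords = base.coords.copy()
pivot = coords[[i for i, a in enumerate(base.atoms)
                if a.resnum == 3 and a.name == "CA"][0]]
rot = Rotation.from_euler("x", 60, degrees=True).as_matrix()
for i, a in enumerate(base.atoms):
    if a.resnum == 3 and a.name in ("CB", "CG"):
        coords[i] = (coords[i] - pivot) @ rot.T + pivot
swung = base.with_coords(coords)

water_ens = gen_perturbed_family(base, 7, sigma=0.15, seed=1)
cosolv_ens = gen_perturbed_family(swung, 7, sigma=0.15, seed=2)

i_w = select_representative(water_ens)
i_c = select_representative(cosolv_ens)
rep_w, rep_c = water_ens[i_w], cosolv_ens[i_c]

table = per_residue_rmsd(rep_w, rep_c, base.residue_ids(),
                         site_label="AF2", probe_label="IPA")
print(f"representatives: water #{i_w}, cosolvent #{i_c}")
print(table[["residue", "rmsd", "n_atoms"]].round(2).to_string(index=False))
print(f"\nmost adapted residue: {table.loc[table['rmsd'].idxmax(), 'residue']}")
# Residue A:3 stands out with the largest heavy-atom RMSD — the probe-induced
# rotamer change — while the other residues stay near the ensemble jitter.
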