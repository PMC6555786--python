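import numpy as np
import pytest

import shiftcodec as sc
from shiftcodec.cs_io import common_scheme
from shiftcodec.preprocess import complete_case_matrix

STAR_V3 = """\
data_test_entry

save_assigned_chemical_shifts
   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts
   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Entity_assembly_ID
      _Atom_chem_shift.Comp_index_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Val

      1 A 1 ALA N  123.40
      2 A 1 ALA C  177.10
      3 A 1 ALA CA  52.30
      4 A 1 ALA CB  18.90
      5 A 1 ALA HN   8.21
      6 A 1 ALA HA   4.12
      7 A 2 GLY N  108.50
      8 A 2 GLY C  173.80
      9 A 2 GLY CA  45.10
     10 A 2 GLY H    8.40
     11 A 2 GLY HA   3.95
     12 A 3 VAL N  120.70
     13 A 3 VAL C  175.90
     14 A 3 VAL CA  62.40
     15 A 3 VAL CB  32.60
     16 A 3 VAL H    8.05
     17 A 3 VAL HA   4.01
   stop_
save_
"""


@pytest.fixture
def star_file(tmp_path):
    path = tmp_path / "entry.str"
    path.write_text(STAR_V3)
    return path


@pytest.fixture(scope="session")
def two_class_pool():
    """Small, well-separated helix/sheet pool for model unit tests."""
    spec = sc.SyntheticSpec.two_class(
        separation=5.0, n_proteins=40, length=(60, 80), seed=11
    )
    tables, truth = sc.generate_dataset(spec)
    return tables, truth


@pytest.fixture(scope="session")
def ala_training_data(two_class_pool):
    """Scaled complete-case matrix and class labels for alanine."""
    tables, truth = two_class_pool
    scheme = common_scheme()
    recs, labels = [], []
    for t in tables:
        for r in t:
            if r.residue_type == "A":
                recs.append(r)
                labels.append(truth.labels[(t.entry_id, r.chain_id, r.residue_number)])
    filt = sc.PercentileFilter(scheme=scheme).fit(recs)
    keep = [not filt.is_outlier(r) for r in recs]
    recs = [r for r, k in zip(recs, keep) if k]
    labels = [l for l, k in zip(labels, keep) if k]
    scaler = sc.ShiftScaler(scheme=scheme).fit(recs)
    X = complete_case_matrix(recs, scheme, "A", scaler)
    return X, np.asarray(labels), scaler


@pytest.fixture(scope="session")
def trained_ala(ala_training_data):
    """Alanine autoencoder trained and oriented on the two-class pool."""
    X, labels, _ = ala_training_data
    model = sc.ResidueAutoencoder("A", seed=3, max_epochs=300)
    model.fit(X)
    model.orient(X, labels)
    return model
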