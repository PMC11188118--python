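import numpy as np
import pytest

import viperpanel as vp


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort shared by read-only tests."""
    config = vp.default_paperlike_config(seed=11, n_trauma=400, n_control=50)
    panel, subjects, truth = vp.generate(config)
    return panel, subjects, truth


@pytest.fixture()
def toy_panel_files(tmp_path):
    """3-subject, 2-analyte toy panel with one empty and one sentinel cell."""
    panel = tmp_path / "panel.csv"
    lods = tmp_path / "lods.csv"
    clinical = tmp_path / "clinical.csv"
    panel.write_text(
        "id,A,B\n"
        "s1,10.0,5.0\n"
        "s2,0.5,\n"  # A below its lower LOD; B missing
        "s3,250.0,<LOD\n"  # A above its upper LOD; B sentinel below
    )
    lods.write_text(
        "analyte,lower_lod,upper_lod,curve_min\n"
        "A,1.0,100.0,0.8\n"
        "B,2.0,50.0,\n"
    )
    clinical.write_text(
        "id,group,age,sex,trauma_level,outcome,mechanism,locations,wound_type,covid\n"
        "s1,trauma,30,male,4,discharged_home,mvc,torso,bone,negative\n"
        "s2,trauma,45,female,1,deceased,fall,head_neck;torso,internal;soft_tissue,untested\n"
        "s3,control,50,male,,unknown,unknown,,,untested\n"
    )
    return panel, lods, clinical
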