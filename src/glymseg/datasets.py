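"""Bundled reference tables.

`load_cohort_breakpoint_table` returns per-region first-appearance estimates
(hours, with 95% CIs) published for a two-cohort intrathecal CSF-tracer MRI
study: 30 reference (REF) subjects and 15 idiopathic-intracranial-
hypertension (IIH) patients, 17 composite brain regions. The raw scan data
behind these estimates are not public; the table supports the package's
reconstruction mode, where the z test on the breakpoint difference is
recomputed from the printed group estimates alone (the SE of each breakpoint
is back-solved from its CI width).

``p`` is the printed two-sided z-test p-value for the group difference;
where the source printed only "< 0.001" the value is stored as 0.001 and
``p_is_upper_bound`` is True.
"""

from io import StringIO

import pandas as pd

_TABLE_CSV = """\
region,psi_ref,ref_lo,ref_hi,r2_ref,psi_iih,iih_lo,iih_hi,diff,diff_lo,diff_hi,p,p_is_upper_bound,r2_joint
frontal cerebral cortex,0.9,0.7,1.2,0.36,0.5,0.1,0.9,-0.5,-0.9,0.0,0.052,False,0.35
frontal white matter,3.4,2.7,4.0,0.03,3.0,2.2,3.7,-0.4,-1.4,0.6,0.412,False,0.08
temporal cerebral cortex,0.7,0.5,1.0,0.35,0.1,-0.4,0.6,-0.6,-1.2,0.0,0.035,False,0.37
temporal white matter,2.1,1.6,2.7,0.09,3.0,2.2,3.7,0.8,-0.1,1.7,0.078,False,0.14
parietal cerebral cortex,1.5,1.1,1.9,0.29,1.8,1.2,2.4,0.3,-0.4,1.0,0.472,False,0.26
parietal white matter,3.4,2.5,4.2,0.03,5.8,5.6,5.9,2.4,1.5,3.3,0.001,True,0.06
occipital cerebral cortex,1.0,0.5,1.5,0.28,1.4,0.3,2.4,0.4,-0.8,1.5,0.522,False,0.26
occipital white matter,2.6,1.5,3.6,0.07,3.0,1.3,4.6,0.4,-1.6,2.4,0.679,False,0.06
entorhinal cerebral cortex,0.3,-0.1,0.7,0.65,-0.1,-0.8,0.6,-0.4,-1.2,0.3,0.273,False,0.69
entorhinal white matter,2.0,1.1,2.8,0.22,2.4,1.7,3.2,0.5,-0.7,1.6,0.424,False,0.45
insular cerebral cortex,0.6,0.3,0.9,0.69,0.1,-0.7,0.8,-0.5,-1.3,0.2,0.175,False,0.67
insular white matter,2.3,0.7,3.9,0.06,5.7,5.5,6.0,3.4,1.8,5.0,0.001,True,0.18
cingulate cerebral cortex,0.7,0.5,0.9,0.53,0.3,-0.2,0.8,-0.5,-1.0,0.1,0.106,False,0.49
cingulate white matter,2.2,1.3,3.0,0.06,3.0,1.7,4.2,0.8,-0.7,2.3,0.281,False,0.08
basal ganglia,2.2,0.8,3.5,0.02,2.9,0.8,4.9,0.7,-1.7,3.2,0.567,False,0.03
limbic structures,0.6,0.3,0.8,0.33,0.0,-0.5,0.5,-0.6,-1.1,-0.1,0.027,False,0.40
choroid plexus,0.2,-0.7,1.1,0.25,-1.1,-3.3,1.1,-1.2,-3.6,1.1,0.304,False,0.25
"""


def load_cohort_breakpoint_table() -> pd.DataFrame:
    """Published per-region breakpoint estimates for the REF and IIH cohorts.

    Columns: region; psi_ref / psi_iih with (ref_lo, ref_hi) / (iih_lo,
    iih_hi) 95% CIs, all in hours; r2_ref (REF-model fit); the printed group
    difference ``diff`` (IIH − REF, hours) with its CI; the printed
    two-sided p (``p_is_upper_bound`` marks "< 0.001" entries); r2_joint for
    the two-group model.
    """
    df = pd.read_csv(StringIO(_TABLE_CSV))
    df["p_is_upper_bound"] = df["p_is_upper_bound"].astype(bool)
    return df
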