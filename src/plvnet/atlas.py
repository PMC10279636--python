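"""Destrieux cortical parcellation labels and face-network node sets.

The whole-brain analysis uses the 148-parcel Destrieux atlas (74 gyral and
sulcal labels per hemisphere).  The face-processing network (FPN) splits
into a *core* system of occipito-temporal regions (occipital face area,
fusiform face area, superior temporal sulcus) and an *extended* system of
distributed regions (superior and inferior frontal gyri, anterior temporal
cortex, insula, secondary sensorimotor cortex).  The shipped assignment
maps those region lists onto Destrieux labels; it is a configuration file,
not code — pass your own two-column CSV to override it.
"""

from __future__ import annotations

from importlib import resources

from .graphs import NodeSetAssignment

__all__ = ["destrieux_labels", "default_face_network", "N_PARCELS"]

N_PARCELS = 148

# 74 Destrieux (2010) labels per hemisphere, FreeSurfer naming
_DESTRIEUX_BASE = [
    "G_and_S_frontomargin", "G_and_S_occipital_inf", "G_and_S_paracentral",
    "G_and_S_subcentral", "G_and_S_transv_frontopol", "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant", "G_and_S_cingul-Mid-Post", "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral", "G_cuneus", "G_front_inf-Opercular",
    "G_front_inf-Orbital", "G_front_inf-Triangul", "G_front_middle",
    "G_front_sup", "G_Ins_lg_and_S_cent_ins", "G_insular_short",
    "G_occipital_middle", "G_occipital_sup", "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual", "G_oc-temp_med-Parahip", "G_orbital",
    "G_pariet_inf-Angular", "G_pariet_inf-Supramar", "G_parietal_sup",
    "G_postcentral", "G_precentral", "G_precuneus", "G_rectus",
    "G_subcallosal", "G_temp_sup-G_T_transv", "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar", "G_temp_sup-Plan_tempo", "G_temporal_inf",
    "G_temporal_middle", "Lat_Fis-ant-Horizont", "Lat_Fis-ant-Vertical",
    "Lat_Fis-post", "Pole_occipital", "Pole_temporal", "S_calcarine",
    "S_central", "S_cingul-Marginalis", "S_circular_insula_ant",
    "S_circular_insula_inf", "S_circular_insula_sup", "S_collat_transv_ant",
    "S_collat_transv_post", "S_front_inf", "S_front_middle", "S_front_sup",
    "S_interm_prim-Jensen", "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus", "S_oc_sup_and_transversal", "S_occipital_ant",
    "S_oc-temp_lat", "S_oc-temp_med_and_Lingual", "S_orbital_lateral",
    "S_orbital_med-olfact", "S_orbital-H_Shaped", "S_parieto_occipital",
    "S_pericallosal", "S_postcentral", "S_precentral-inf-part",
    "S_precentral-sup-part", "S_suborbital", "S_subparietal",
    "S_temporal_inf", "S_temporal_sup", "S_temporal_transverse",
]


def destrieux_labels() -> list[str]:
    """The 148 Destrieux parcel labels (lh_ then rh_ prefixed)."""
    return [f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DESTRIEUX_BASE]


def default_face_network() -> NodeSetAssignment:
    """Best-effort core/extended FPN assignment on Destrieux labels."""
    path = resources.files("plvnet").joinpath("data/face_network_nodes.csv")
    with resources.as_file(path) as p:
        return NodeSetAssignment.from_csv(p)
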