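"""Region atlas for the hemisphere of interest.

The analysis operates on 47 AAL2-style regions of a single hemisphere,
with a named sensorimotor subset (M1, S1, SMA, thalamus, caudate,
putamen, pallidum) and one negative-control region (inferior occipital
gyrus, IOG) used to establish functional specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Left-hemisphere AAL2 cortical + subcortical regions retained after
# dropping sub-cerebellar parcels (47 regions).
DEFAULT_LABELS = (
    "Precentral_L",
    "Frontal_Sup_2_L",
    "Frontal_Mid_2_L",
    "Frontal_Inf_Oper_L",
    "Frontal_Inf_Tri_L",
    "Frontal_Inf_Orb_2_L",
    "Rolandic_Oper_L",
    "Supp_Motor_Area_L",
    "Olfactory_L",
    "Frontal_Sup_Medial_L",
    "Frontal_Med_Orb_L",
    "Rectus_L",
    "OFCmed_L",
    "OFCant_L",
    "OFCpost_L",
    "OFClat_L",
    "Insula_L",
    "Cingulate_Ant_L",
    "Cingulate_Mid_L",
    "Cingulate_Post_L",
    "Hippocampus_L",
    "ParaHippocampal_L",
    "Amygdala_L",
    "Calcarine_L",
    "Cuneus_L",
    "Lingual_L",
    "Occipital_Sup_L",
    "Occipital_Mid_L",
    "Occipital_Inf_L",
    "Fusiform_L",
    "Postcentral_L",
    "Parietal_Sup_L",
    "Parietal_Inf_L",
    "SupraMarginal_L",
    "Angular_L",
    "Precuneus_L",
    "Paracentral_Lobule_L",
    "Caudate_L",
    "Putamen_L",
    "Pallidum_L",
    "Thalamus_L",
    "Heschl_L",
    "Temporal_Sup_L",
    "Temporal_Pole_Sup_L",
    "Temporal_Mid_L",
    "Temporal_Pole_Mid_L",
    "Temporal_Inf_L",
)

DEFAULT_SENSORIMOTOR = {
    "M1": "Precentral_L",
    "S1": "Postcentral_L",
    "SMA": "Supp_Motor_Area_L",
    "thalamus": "Thalamus_L",
    "caudate": "Caudate_L",
    "putamen": "Putamen_L",
    "pallidum": "Pallidum_L",
}

DEFAULT_CONTROL = ("IOG", "Occipital_Inf_L")


@dataclass(frozen=True)
class NodeAtlas:
    """Region labels plus the named sensorimotor subset and control node.

    ``sensorimotor`` maps role names (M1, S1, ...) to region labels;
    ``control`` is the (role, label) pair for the negative-control node.
    """

    all_labels: tuple = DEFAULT_LABELS
    sensorimotor: dict = field(default_factory=lambda: dict(DEFAULT_SENSORIMOTOR))
    control: tuple = DEFAULT_CONTROL

    def __post_init__(self):
        object.__setattr__(self, "all_labels", tuple(str(x) for x in self.all_labels))
        labels = set(self.all_labels)
        if len(labels) != len(self.all_labels):
            raise ValueError("atlas labels must be unique")
        subset = list(self.sensorimotor.values()) + [self.control[1]]
        if len(set(subset)) != len(subset):
            raise ValueError("sensorimotor/control labels must not repeat")
        missing = [lab for lab in subset if lab not in labels]
        if missing:
            raise ValueError(f"atlas subset labels missing from all_labels: {missing}")

    @property
    def n(self) -> int:
        return len(self.all_labels)

    @property
    def sensorimotor_labels(self) -> tuple:
        return tuple(self.sensorimotor.values())

    @property
    def control_label(self) -> str:
        return self.control[1]

    @property
    def node_labels(self) -> tuple:
        """The 8 analysed nodes: sensorimotor subset plus control."""
        return self.sensorimotor_labels + (self.control_label,)

    def role_of(self, label: str) -> str:
        for role, lab in self.sensorimotor.items():
            if lab == label:
                return role
        if label == self.control_label:
            return self.control[0]
        return label

    def label_of(self, role: str) -> str:
        if role in self.sensorimotor:
            return self.sensorimotor[role]
        if role == self.control[0]:
            return self.control[1]
        raise KeyError(role)


def default_atlas() -> NodeAtlas:
    return NodeAtlas()


def read_atlas(labels_path, roles_path=None) -> NodeAtlas:
    """Load an atlas from a plain-text label list plus a YAML role file.

    ``labels_path``: one region label per line.  ``roles_path`` (optional):
    YAML mapping with keys ``sensorimotor`` (role -> label) and ``control``
    ([role, label]); defaults are used when omitted.
    """
    labels = [
        line.strip()
        for line in Path(labels_path).read_text().splitlines()
        if line.strip()
    ]
    sensorimotor = dict(DEFAULT_SENSORIMOTOR)
    control = DEFAULT_CONTROL
    if roles_path is not None:
        cfg = yaml.safe_load(Path(roles_path).read_text()) or {}
        if "sensorimotor" in cfg:
            sensorimotor = {str(k): str(v) for k, v in cfg["sensorimotor"].items()}
        if "control" in cfg:
            control = (str(cfg["control"][0]), str(cfg["control"][1]))
    return NodeAtlas(tuple(labels), sensorimotor, control)


def write_atlas(atlas: NodeAtlas, labels_path, roles_path) -> None:
    Path(labels_path).write_text("\n".join(atlas.all_labels) + "\n")
    Path(roles_path).write_text(
        yaml.safe_dump(
            {"sensorimotor": atlas.sensorimotor, "control": list(atlas.control)},
            sort_keys=False,
        )
    )
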