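"""HDF5 cohort container and TSV exports.

One file per cohort: a ``group`` group (maps, amplitudes, netmat, variances),
one ``subjects/NNN`` group per subject (maps, amplitudes, timecourses), and
top-level behaviour / confounds / family / latent arrays plus the generating
spec as attributes.  Behaviour and confounds are additionally exportable as
TSV with subjects as rows; netmats and node timeseries export as TSV with a
JSON sidecar carrying metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .extraction import NodeTimeseries
from .netmats import Netmat
from .synthetic_cohort import Cohort, CohortSpec, GroupModel, ModeDecomposition

__all__ = [
    "save_cohort",
    "load_cohort",
    "behaviour_to_tsv",
    "netmat_to_tsv",
    "netmat_from_tsv",
    "timeseries_to_tsv",
]


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("group")
        g.create_dataset("maps", data=cohort.group.group_maps)
        g.create_dataset("amplitudes", data=cohort.group.group_amplitudes)
        g.create_dataset("netmat", data=cohort.group.group_netmat)
        g.create_dataset("variances", data=cohort.group.group_variances)
        g.attrs["noise_var"] = cohort.group.noise_var
        subs = f.create_group("subjects")
        for i, s in enumerate(cohort.subjects):
            sg = subs.create_group(f"{i:04d}")
            sg.create_dataset("maps", data=s.maps)
            sg.create_dataset("amplitudes", data=s.amplitudes)
            sg.create_dataset("timecourses", data=s.timecourses)
        f.create_dataset("behaviour", data=cohort.behaviour)
        f.create_dataset("confounds", data=cohort.confounds)
        f.create_dataset("family_id", data=cohort.family_id)
        f.create_dataset("latent", data=cohort.latent)
        if cohort.netmats is not None:
            f.create_dataset("netmats", data=cohort.netmats)
        if cohort.map_perturbation_weights is not None:
            f.create_dataset("map_perturbation_weights", data=cohort.map_perturbation_weights)
        if cohort.behaviour_loadings_true is not None:
            f.create_dataset("behaviour_loadings_true", data=cohort.behaviour_loadings_true)
        if cohort.spec is not None:
            f.attrs["spec"] = json.dumps(dataclasses.asdict(cohort.spec))


def load_cohort(path: str | Path) -> Cohort:
    with h5py.File(path, "r") as f:
        group = GroupModel(
            group_maps=f["group/maps"][:],
            group_amplitudes=f["group/amplitudes"][:],
            group_netmat=f["group/netmat"][:],
            noise_var=float(f["group"].attrs["noise_var"]),
            group_variances=f["group/variances"][:],
        )
        subjects = [
            ModeDecomposition(
                maps=f[f"subjects/{k}/maps"][:],
                amplitudes=f[f"subjects/{k}/amplitudes"][:],
                timecourses=f[f"subjects/{k}/timecourses"][:],
            )
            for k in sorted(f["subjects"])
        ]
        spec = None
        if "spec" in f.attrs:
            spec = CohortSpec(**json.loads(f.attrs["spec"]))
        return Cohort(
            subjects=subjects,
            group=group,
            behaviour=f["behaviour"][:],
            confounds=f["confounds"][:],
            family_id=f["family_id"][:],
            latent=f["latent"][:],
            spec=spec,
            netmats=f["netmats"][:] if "netmats" in f else None,
            map_perturbation_weights=(
                f["map_perturbation_weights"][:] if "map_perturbation_weights" in f else None
            ),
            behaviour_loadings_true=(
                f["behaviour_loadings_true"][:] if "behaviour_loadings_true" in f else None
            ),
        )


def behaviour_to_tsv(cohort: Cohort, path: str | Path) -> None:
    """Behaviour + confounds as TSV, subjects as rows, header row included."""
    n_b = cohort.behaviour.shape[1]
    n_c = cohort.confounds.shape[1]
    df = pd.DataFrame(
        np.column_stack([cohort.behaviour, cohort.confounds, cohort.family_id]),
        columns=[f"behaviour_{i}" for i in range(n_b)]
        + [f"confound_{i}" for i in range(n_c)]
        + ["family_id"],
    )
    df.to_csv(path, sep="\t", index_label="subject")


def netmat_to_tsv(net: Netmat, path: str | Path, node_names: list[str] | None = None) -> None:
    names = node_names or [f"node_{i}" for i in range(net.n_nodes)]
    pd.DataFrame(net.values, index=names, columns=names).to_csv(path, sep="\t")
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps({"kind": net.kind, "rho": net.rho, "z_transformed": net.z_transformed})
    )


def netmat_from_tsv(path: str | Path) -> Netmat:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return Netmat(values=df.values, **meta)


def timeseries_to_tsv(ts: NodeTimeseries, path: str | Path, node_names: list[str] | None = None) -> None:
    names = node_names or [f"node_{i}" for i in range(ts.n_nodes)]
    pd.DataFrame(ts.values, columns=names).to_csv(path, sep="\t", index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({"node_order": names, "run_offsets": ts.run_offsets}))
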