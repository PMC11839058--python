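"""Readers and writers for the standard on-disk formats.

Volumes are NIfTI (via nibabel), meshes PLY (via trimesh) or GIFTI (via
nibabel.gifti), tables CSV with documented column names.  These are thin
wrappers so the rest of the package works on arrays and DataFrames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .axis import SurfaceMesh


def save_nifti(volume: np.ndarray, path, voxel_size: float = 1.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    nib.save(img, str(path))


def load_nifti(path):
    """Returns (data array, isotropic voxel size in mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), float(zooms[0])


def save_mesh_ply(mesh: SurfaceMesh, path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(path), file_type="ply", encoding="ascii")


def save_mesh_gifti(mesh: SurfaceMesh, path) -> None:
    import nibabel as nib
    from nibabel import gifti

    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            gifti.GiftiDataArray(
                mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def load_mesh(path, vertex_parcel=None) -> SurfaceMesh:
    """Load a PLY or GIFTI surface; ``vertex_parcel`` optionally points to a
    CSV with columns ``vertex, parcel``."""
    path = str(path)
    if path.endswith(".gii"):
        import nibabel as nib

        img = nib.load(path)
        vertices = img.darrays[0].data
        triangles = img.darrays[1].data
    else:
        import trimesh

        tm = trimesh.load(path, process=False)
        vertices, triangles = np.asarray(tm.vertices), np.asarray(tm.faces)
    labels = None
    if vertex_parcel is not None:
        tab = pd.read_csv(vertex_parcel).sort_values("vertex")
        labels = tab["parcel"].to_numpy()
    return SurfaceMesh(vertices=vertices, triangles=triangles, vertex_parcel=labels)


def save_vertex_labels(mesh: SurfaceMesh, path) -> None:
    pd.DataFrame(
        {"vertex": np.arange(mesh.n_vertices), "parcel": mesh.vertex_parcel}
    ).to_csv(path, index=False)
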