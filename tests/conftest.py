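"""Shared fixtures: small hand-built meshes and one cached synthetic subject.

All fixtures are generated programmatically; nothing is read from disk.
"""

import numpy as np
import pytest

from cgrid import (
    FlatMesh,
    LabelDialect,
    SubjectSpec,
    extract_smx_borders,
    make_subject,
)

APARC = LabelDialect.freesurfer_aparc()


def triangulated_rectangle(nx, ny, spacing=1.0, label="precentral"):
    """A structured triangulated grid mesh with one label everywhere."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    return FlatMesh(verts, faces, [label] * (nx * ny))


def labeled_strip(nx=9, ny=12, spacing=1.0):
    """A two-label strip: left columns 'A', right columns 'B'."""
    mesh = triangulated_rectangle(nx, ny, spacing)
    labels = []
    for i in range(nx):
        labels.extend(["A" if i < nx // 2 else "B"] * ny)
    mesh.labels = labels
    return mesh


@pytest.fixture(scope="session")
def aparc():
    return APARC


@pytest.fixture(scope="session")
def subject():
    """One moderately warped synthetic subject, reused across tests."""
    return make_subject(SubjectSpec(seed=11))


@pytest.fixture(scope="session")
def subject_borders(subject, aparc):
    return extract_smx_borders(subject.mesh, aparc)


@pytest.fixture(scope="session")
def flat_subject():
    """An unwarped (identity) subject: borders are straight vertical lines."""
    return make_subject(SubjectSpec(seed=5, warp_amplitude=0.0))
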