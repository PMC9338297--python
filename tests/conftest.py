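"""Shared fixtures and digital-phantom helpers."""

import numpy as np
import pytest

from spiralflow.graph import Node, Segment, VascularGraph


def digital_cylinder(radius_vox=5, length_vox=100, pad=4, center_offset=0.0):
    """Axis-aligned solid cylinder mask; axis along axis 0 through voxel
    centers (plus an optional sub-voxel lateral offset)."""
    n = 2 * (int(np.ceil(radius_vox)) + pad) + 1
    c = (n - 1) / 2 + center_offset
    shape = (length_vox + 2 * pad, n, n)
    zz, yy, xx = np.indices(shape)
    mask = ((yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2) & (zz >= pad) & (
        zz < pad + length_vox
    )
    return mask, c


def digital_torus(ring_radius=15, tube_radius=4, pad=4):
    n = 2 * (ring_radius + tube_radius + pad) + 1
    m = 2 * (tube_radius + pad) + 1
    yy, xx, zz = np.indices((n, n, m))
    c = ring_radius + tube_radius + pad
    rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    return (rho - ring_radius) ** 2 + (zz - tube_radius - pad) ** 2 <= tube_radius**2


def capsule_mask(shape, p0, p1, r):
    """Solid capsule (cylinder with spherical caps) between two points."""
    zz, yy, xx = np.indices(shape)
    pts = np.stack([zz, yy, xx], -1).astype(float)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0, 1)
    closest = p0 + t[..., None] * d
    return ((pts - closest) ** 2).sum(-1) <= r * r


def y_mask():
    """Three thick branches meeting at one junction."""
    shape = (80, 80, 40)
    return (
        capsule_mask(shape, (10, 40, 20), (40, 40, 20), 4)
        | capsule_mask(shape, (40, 40, 20), (70, 20, 20), 4)
        | capsule_mask(shape, (40, 40, 20), (70, 60, 20), 4)
    )


def path_graph(n_segments, first_node=0, first_segment=0, voxel_size_um=1.0, length_um=20.0):
    """A chain of ``n_segments`` two-node segments sharing junction nodes."""
    g = VascularGraph(voxel_size_um=voxel_size_um)
    for i in range(n_segments + 1):
        g.nodes[first_node + i] = Node(
            position=np.array([first_node * 1000.0 + i * length_um, 0.0, 0.0]),
            radius_um=15.0,
        )
    for i in range(n_segments):
        g.segments[first_segment + i] = Segment(
            chain=[first_node + i, first_node + i + 1], vessel_class=1
        )
    return g


def merge_graphs(graphs, voxel_size_um=1.0):
    out = VascularGraph(voxel_size_um=voxel_size_um)
    for g in graphs:
        out.nodes.update(g.nodes)
        out.segments.update(g.segments)
    return out


@pytest.fixture(scope="session")
def calibration():
    from spiralflow.radius import default_calibration

    return default_calibration()


@pytest.fixture(scope="session")
def site_phantom():
    from spiralflow.phantoms import make_site_phantom

    return make_site_phantom(7, voxel_size_um=8.0, noise_sd=10.0)


@pytest.fixture(scope="session")
def site_graph(site_phantom):
    """Pruned (not yet resampled) graph of the session site phantom."""
    from scipy import ndimage

    from spiralflow.graph import build_graph, prune_spurious
    from spiralflow.skeleton import skeletonize

    labels = site_phantom.labels
    mask = labels.class_mask((1, 2, 3, 4))
    g = build_graph(skeletonize(mask), labels)
    edt = ndimage.distance_transform_edt(mask) * labels.voxel_size_um
    for node in g.nodes.values():
        if node.voxel is not None:
            node.radius_um = float(edt[node.voxel])
    g = prune_spurious(g)
    for node in g.nodes.values():
        node.radius_um = float("nan")
    return g
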