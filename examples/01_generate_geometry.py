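"""Build the two tissue geometries: a random collagen-fiber network (ECM)
and a packing of ellipsoidal tumor cells with spherical stromal cells.

Prints the realized porosity / cell fraction and the pore connectivity —
the fraction of fluid nodes in the largest connected pore component, which
controls whether particles can percolate through the structure.
"""

from nanodiff.geometry import (
    GeometrySpec,
    apply_degradation,
    generate_ecm,
    generate_tumor,
    measure_connectivity,
)

ecm = generate_ecm(
    GeometrySpec(domain_kind="ecm", shape=(50, 50, 50), spacing=50e-9,
                 target_porosity=0.94, seed=1)
)
print(f"ECM 2.5 um box, 100 nm fibers: porosity = {ecm.porosity:.4f}, "
      f"pore connectivity = {measure_connectivity(ecm):.4f}")

degraded = apply_degradation(ecm, n_points=125, segment_length=200e-9, seed=2)
print(f"after 125 x 200 nm degradation points: porosity = {degraded.porosity:.4f}")

tumor = generate_tumor(
    GeometrySpec(domain_kind="tumor", shape=(64, 64, 64), spacing=1e-6,
                 cell_volume_fraction=0.21, seed=3)
)
print(f"tumor 64 um box, 4:1 tumor:stromal cells: cell fraction = "
      f"{1 - tumor.porosity:.4f}, pore connectivity = {measure_connectivity(tumor):.4f}")

# porosity is the fluid fraction; connectivity near 1 means a single
# percolating pore space, which the particle ensembles require to diffuse.
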