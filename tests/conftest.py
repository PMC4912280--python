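"""Shared fixtures: tiny volumes, small phantoms, synthetic DICOM series."""

import numpy as np
import pytest

from neckquant import (
    CTVolume,
    Ellipsoid,
    EllipticCylinder,
    LandmarkSet,
    PhantomSpec,
    Tube,
    generate_phantom,
)


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return CTVolume(voxels=np.asarray(values, dtype=float), spacing=spacing, origin=origin)


def uniform_volume(hu, shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
    return make_volume(np.full(shape, float(hu)), spacing=spacing)


def simple_landmarks(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0), seed_xyz=None):
    """Landmarks spanning the full grid of a small test volume."""
    z_top = (shape[2] - 1) * spacing[2]
    x_top = (shape[0] - 1) * spacing[0]
    return LandmarkSet(
        z_orbit_roof=z_top,
        z_sternal_angle=0.0,
        x_left_midclavicle=0.0,
        x_right_midclavicle=x_top,
        z_hard_palate=z_top,
        z_first_tracheal_ring=0.0,
        z_soft_palate_tip=0.7 * z_top,
        z_thyroid_cartilage=0.3 * z_top,
        airway_seed=seed_xyz or (shape[0] // 2, shape[1] // 2, shape[2] // 2),
    )


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A compact neck-like phantom: body cylinder, one fat ellipsoid, airway."""
    body = EllipticCylinder(center_xy=(0.0, 0.0), semi_axes_xy=(40.0, 36.0), z_range=(2.0, 97.0))
    fat = Ellipsoid(center=(22.0, 0.0, 50.0), semi_axes=(12.0, 12.0, 20.0),
                    compartment="subcutaneous")
    airway = Tube(center_xy=(0.0, 0.0), radius=6.0, z_range=(19.5, 79.5))
    landmarks = LandmarkSet(
        z_orbit_roof=97.0,
        z_sternal_angle=2.0,
        x_left_midclavicle=-45.0,
        x_right_midclavicle=45.0,
        z_hard_palate=79.5,
        z_first_tracheal_ring=19.5,
        z_soft_palate_tip=65.0,
        z_thyroid_cartilage=35.0,
        airway_seed=(0.0, 0.0, 50.0),
    )
    return PhantomSpec(
        grid_shape=(100, 90, 100),
        spacing=(1.0, 1.0, 1.0),
        origin=(-49.5, -44.5, 0.0),
        body=body,
        fat_structures=(fat,),
        airway=airway,
        noise_sd=0.0,
        seed=11,
        landmarks=landmarks,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


def write_dicom_series(dirpath, stored, spacing=(0.7, 0.8, 2.0), slope=1.0,
                       intercept=-1024.0, series_uid="1.2.3.4"):
    """Write a synthetic axial DICOM series from a (nx, ny, nz) stored-value grid."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    stored = np.asarray(stored)
    nx, ny, nz = stored.shape
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [spacing[1], spacing[0]]  # [row (y), col (x)]
        ds.SliceThickness = spacing[2]
        ds.ImagePositionPatient = [0.0, 0.0, k * spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored[:, :, k].T.astype(np.uint16).tobytes()
        ds.save_as(str(dirpath / f"slice_{k:03d}.dcm"), enforce_file_format=True)
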