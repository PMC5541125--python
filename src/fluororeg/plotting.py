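"""Quick-look overlays (matplotlib, imported lazily)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_registration_overlay"]


def plot_registration_overlay(
    image, contour, model: "ContourRegistration", pose, view: int, ax=None
):
    """Plot a view image with the segmented contour and projected outline.

    Returns the matplotlib axes (figure created on demand); useful for
    checking a registration by eye.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(image), cmap="gray", origin="upper")
    ax.plot(contour.points[:, 0], contour.points[:, 1], ".", ms=2, color="tab:orange",
            label="segmented contour")
    p2, _ = model.sampler.sample(model.cam_poses[view] @ pose, n_samples=400)
    ax.plot(p2[:, 0], p2[:, 1], ".", ms=2, color="tab:cyan", label="model outline")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_axis_off()
    return ax
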