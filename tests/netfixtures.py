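"""Network factories used by dotted-import resolution tests."""

import numpy as np

from im2im.nn import ConvNd, Module


class TinyNet(Module):
    def __init__(self, in_channels=1, out_channels=1):
        super().__init__()
        self.conv = ConvNd(2, in_channels, out_channels, 3,
                           np.random.default_rng(0))

    def forward(self, x):
        return self.conv(x)


def make_tiny_net(in_channels=1, out_channels=1):
    return TinyNet(in_channels, out_channels)
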