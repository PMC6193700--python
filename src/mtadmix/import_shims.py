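"""Submodule access helpers.

The package namespace re-exports the ``shd`` *function*, which shadows the
``mtadmix.shd`` submodule attribute; internal code imports the module
through here instead.
"""

import importlib

shd_module = importlib.import_module("mtadmix.shd")
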