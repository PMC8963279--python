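"""Inspect a corpus with type pathologies and derive an index mapping.

The synthetic source mixes integer and float scores (promoted to `float`),
and injects a field that is a plain string in some documents and a subtree
in others — an object/scalar conflict, excluded from the mapping so it
stays stored but unqueryable.
"""

import tempfile

from annohub import generate_mapping, inspect_documents
from annohub.fixtures import FixtureSpec, SourceRecipe, generate_fixture

spec = FixtureSpec(
    seed=11,
    sources=[SourceRecipe(
        name="demo", n_docs=20, with_list_field=True,
        mixed_type_probability=0.5, inject_conflict=True,
    )],
)
truth = generate_fixture(spec, tempfile.mkdtemp())
docs = list(truth.docs_per_source["demo"].values())

report = inspect_documents(docs)
for path in report.paths():
    profile = report.profiles[path]
    flag = " [list]" if profile.in_list else ""
    print(f"{path}: {sorted(profile.observed)}{flag} in {profile.doc_count} doc(s)")

mapping = generate_mapping(report)
print("\nmapped types:", mapping.types)
print("excluded:", mapping.excluded)
# `score` maps to float (int/float mix); `extra` is excluded as a conflict.
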