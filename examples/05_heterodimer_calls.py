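"""Pair passing subunits into heterodimer targets with evidence classes.

Strict mode requires both chains of a receptor to pass the subunit filter;
relaxed mode accepts one passing chain.  RNA- and IHC-derived calls merge
into evidence classes rna_only / ihc_only / both.
"""

from dimertarget import call_relaxed, call_strict, calls_table, load_catalog, load_pairing_rules

catalog = load_catalog()
rules = load_pairing_rules(catalog=catalog)

rna_pass = {"ITGA6", "ITGB4", "ITGAV"}
ihc_pass = {"ITGA6", "ITGB4", "ITGB5"}

print("strict RNA calls:", sorted(call_strict(rna_pass, rules, catalog)))
print("relaxed RNA calls:", sorted(call_relaxed(rna_pass, rules, catalog).items()))

table = calls_table("LIHC", rna_pass, ihc_pass, rules, catalog, mode="strict")
print(table.to_string(index=False))
# α6β4 is called by both modalities ("both"); αv needs a passing β partner
# in strict mode, so its receptors only appear under relaxed calling.
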