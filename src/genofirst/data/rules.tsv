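# Codified familial breast-cancer genetic-testing eligibility rules.
# A versioned approximation of 2018-era familial-BC testing criteria (base)
# plus the adjusted extension (all pancreatic and prostate cancer in family
# history; relative BC onset up to age 60). Edit rows to change the rule set;
# the engine interprets kinds: simple, bc50_combo, tnbc, multi_bc_lineage.
# max_onset_age blank = any age. versions: both | base | adjusted.
rule_id	kind	scope	cancer_type	max_onset_age	min_count	versions
personal_bc_le45	simple	personal	breast	45	1	both
personal_bc_le50_plus	bc50_combo	personal	breast	50	1	both
personal_tnbc_le60	tnbc	personal	breast	60	1	both
personal_oc_any	simple	personal	ovarian		1	both
personal_male_bc	simple	personal	male_breast		1	both
family_bc_le50	simple	family	breast	50	1	both
family_oc_any	simple	family	ovarian		1	both
family_male_bc	simple	family	male_breast		1	both
family_three_bc_lineage	multi_bc_lineage	family	breast		3	both
family_prostate_any	simple	family	prostate		1	adjusted
family_pancreatic_any	simple	family	pancreatic		1	adjusted
family_bc_le60	simple	family	breast	60	1	adjusted
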