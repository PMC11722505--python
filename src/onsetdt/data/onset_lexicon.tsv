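# Clock times assigned to vague onset-period phrases.
# AHA rows follow the American Heart Association key data elements for
# chest pain; EXTENDED rows are local additions for common phrasings.
# phrase	clock_time	source
morning	07:00	AHA
lunch time	12:00	AHA
afternoon	15:00	AHA
dinner time	18:00	AHA
evening	22:00	AHA
awaken from sleep	03:00	AHA
midmorning	09:00	EXTENDED
wake up in the morning	06:00	EXTENDED
after lunch	13:00	EXTENDED
after dinner	19:00	EXTENDED
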