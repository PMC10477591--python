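sample_id	group	age	gender
SRR8873486	non-mCRC	68	Male
SRR8873495	non-mCRC	74	Male
SRR8873494	non-mCRC	68	Male
SRR8873483	non-mCRC	65	Female
SRR8873496	non-mCRC	66	Female
SRR8873491	non-mCRC	38	Male
SRR8873490	non-mCRC	54	Female
SRR8873493	mCRC	44	Female
SRR8873492	mCRC	70	Male
SRR8873487	mCRC	82	Female
SRR8873484	mCRC	85	Male
SRR8873489	mCRC	56	Female
SRR8873488	mCRC	73	Male
SRR8873498	mCRC	32	Male
SRR8873485	mCRC	61	Female
SRR8873497	mCRC	68	Male
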