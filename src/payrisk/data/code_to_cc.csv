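code,cc
D001,CC01
D002,CC01
D003,CC01
D004,CC01
D005,CC02
D006,CC02
D007,CC02
D008,CC02
D009,CC03
D010,CC03
D011,CC03
D012,CC03
D013,CC04
D014,CC04
D015,CC04
D016,CC04
D017,CC05
D018,CC05
D019,CC05
D020,CC05
D021,CC06
D022,CC06
D023,CC06
D024,CC06
D025,CC07
D026,CC07
D027,CC07
D028,CC07
D029,CC08
D030,CC08
D031,CC08
D032,CC08
D033,CC09
D034,CC09
D035,CC09
D036,CC09
D037,CC10
D038,CC10
D039,CC10
D040,CC10
D041,CC11
D042,CC11
D043,CC11
D044,CC11
D045,CC12
D046,CC12
D047,CC12
D048,CC12
D049,CC01
D050,CC02
D051,CC03
D052,CC04
D053,CC05
D054,CC06
D055,CC07
D056,CC08
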