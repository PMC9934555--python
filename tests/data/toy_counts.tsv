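variant	tile	condition	replicate	count	depth
p.D5N	tile1	nonselect	1	1000	1000000
p.D5N	tile1	select	1	100	1000000
p.D5N	tile1	nonselect	2	1000	1000000
p.D5N	tile1	select	2	100	1000000
p.E6K	tile1	nonselect	1	40	1000000
p.E6K	tile1	select	1	4	1000000
p.E6K	tile1	nonselect	2	40	1000000
p.E6K	tile1	select	2	4	1000000
p.F7L	tile1	nonselect	1	250	1000000
p.F7L	tile1	select	1	250	1000000
p.F7L	tile1	nonselect	2	250	1000000
p.F7L	tile1	select	2	250	1000000
p.H8Y	tile1	nonselect	1	1000	1000000
p.H8Y	tile1	select	1	600	1000000
p.H8Y	tile1	nonselect	2	1000	1000000
p.H8Y	tile1	select	2	2	1000000
p.I9V	tile1	nonselect	1	1000	1000000
p.I9V	tile1	select	1	0	1000000
p.I9V	tile1	nonselect	2	1000	1000000
p.I9V	tile1	select	2	0	1000000
p.A10=	tile1	nonselect	1	1000	1000000
p.A10=	tile1	select	1	1000	1000000
p.A10=	tile1	nonselect	2	1000	1000000
p.A10=	tile1	select	2	1000	1000000
p.K11R	tile1	nonselect	1	1000	1000000
p.K11R	tile1	select	1	1000	1000000
p.K11R	tile1	nonselect	2	1000	1000000
p.K11R	tile1	select	2	1000	1000000
p.M12T	tile1	nonselect	1	8	1000000
p.M12T	tile1	select	1	1	1000000
p.M12T	tile1	nonselect	2	8	1000000
p.M12T	tile1	select	2	1	1000000
p.P15Q	tile1	nonselect	1	600	1000000
p.P15Q	tile1	select	1	300	1000000
p.P15Q	tile1	nonselect	2	600	1000000
p.P15Q	tile1	select	2	300	1000000
p.Q16E	tile1	nonselect	1	1000	1000000
p.Q16E	tile1	select	1	50	1000000
p.Q16E	tile1	nonselect	2	1000	1000000
p.Q16E	tile1	select	2	50	1000000
p.V17A	tile1	nonselect	1	400	1000000
p.V17A	tile1	select	1	40	1000000
p.V17A	tile1	nonselect	2	400	1000000
p.V17A	tile1	select	2	40	1000000
p.W18C	tile1	nonselect	1	1000	1000000
p.W18C	tile1	select	1	2000	1000000
p.W18C	tile1	nonselect	2	1000	1000000
p.W18C	tile1	select	2	2000	1000000
p.Y19F	tile1	nonselect	1	100	1000000
p.Y19F	tile1	select	1	10	1000000
p.Y19F	tile1	nonselect	2	100	1000000
p.Y19F	tile1	select	2	10	1000000
p.G20=	tile1	nonselect	1	800	1000000
p.G20=	tile1	select	1	800	1000000
p.G20=	tile1	nonselect	2	800	1000000
p.G20=	tile1	select	2	800	1000000
p.C21G	tile1	nonselect	1	5000	1000000
p.C21G	tile1	select	1	500	1000000
p.C21G	tile1	nonselect	2	5000	1000000
p.C21G	tile1	select	2	500	1000000
p.L30=	tile1	nonselect	1	1200	1000000
p.L30=	tile1	select	1	1200	1000000
p.L30=	tile1	nonselect	2	1200	1000000
p.L30=	tile1	select	2	1200	1000000
p.K40*	tile1	nonselect	1	1000	1000000
p.K40*	tile1	select	1	10	1000000
p.K40*	tile1	nonselect	2	1000	1000000
p.K40*	tile1	select	2	10	1000000
p.R50*	tile1	nonselect	1	500	1000000
p.R50*	tile1	select	1	5	1000000
p.R50*	tile1	nonselect	2	500	1000000
p.R50*	tile1	select	2	5	1000000
p.S60*	tile1	nonselect	1	2000	1000000
p.S60*	tile1	select	1	20	1000000
p.S60*	tile1	nonselect	2	2000	1000000
p.S60*	tile1	select	2	20	1000000
p.T90*	tile1	nonselect	1	1000	1000000
p.T90*	tile1	select	1	500	1000000
p.T90*	tile1	nonselect	2	1000	1000000
p.T90*	tile1	select	2	500	1000000
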