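The Hare and the Tortoise

The Hare was once boasting of his speed before the other animals. I have
never yet been beaten, said he, when I put forth my full speed. I challenge
any one here to race with me. The Tortoise said quietly, I accept your
challenge. That is a good joke, said the Hare. I could dance round you all
the way. Keep your boasting till you have beaten me, answered the Tortoise.
Shall we race? So a course was fixed and a start was made. The Hare darted
almost out of sight at once, but soon stopped and, to show his contempt for
the Tortoise, lay down to have a nap. The Tortoise plodded on and plodded
on, and when the Hare awoke from his nap, he saw the Tortoise just near the
winning post and could not run up in time to save the race. Then said the
Tortoise, plodding wins the race.

The Dog and the Shadow

It happened that a Dog had got a piece of meat and was carrying it home in
his mouth to eat it in peace. Now on his way home he had to cross a plank
lying across a running brook. As he crossed, he looked down and saw his own
shadow reflected in the water beneath. Thinking it was another dog with
another piece of meat, he made up his mind to have that also. So he made a
snap at the shadow in the water, but as he opened his mouth the piece of
meat fell out, dropped into the water and was never seen more. Beware lest
you lose the substance by grasping at the shadow.

The Wind and the Sun

The Wind and the Sun were disputing which was the stronger. Suddenly they
saw a traveller coming down the road, and the Sun said, I see a way to
decide our dispute. Whichever of us can cause that traveller to take off
his cloak shall be regarded as the stronger. You begin. So the Sun retired
behind a cloud, and the Wind began to blow as hard as it could upon the
traveller. But the harder he blew the more closely did the traveller wrap
his cloak round him, till at last the Wind had to give up in despair. Then
the Sun came out and shone in all his glory upon the traveller, who soon
found it too hot to walk with his cloak on. Kindness effects more than
severity.
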